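"""Rasters, displacement fields, manifests and metric reports.

Conventions (asserted here, imported everywhere):

* images ("rasters") are H x W float arrays with intensities in [0, 1];
  row 0 is the top of the image, column 0 the left, indices are 0-based;
* masks are H x W uint8 arrays with values in {0, 1};
* displacement fields are backward maps in pixel units: the warped output
  at pixel p samples the input at p + (dx, dy), where dx displaces the
  column coordinate and dy the row coordinate.

The field container is a small self-describing binary: a 4-byte magic
``LRF1``, little-endian uint32 height and width, then the dx plane and the
dy plane as little-endian float32, row-major.  Round trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError

FIELD_MAGIC = b"LRF1"

#: Axis/order conventions, importable so other modules never restate them.
ROW_AXIS = 0
COL_AXIS = 1


# ---------------------------------------------------------------------------
# validation helpers


def validate_raster(pixels: np.ndarray) -> np.ndarray:
    """Check Raster2D invariants and return a float64 view/copy."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise FormatError(f"raster must be 2-D with H,W >= 2, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise FormatError("raster contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise FormatError("raster intensities must lie in [0, 1]")
    return arr


def validate_mask(pixels: np.ndarray) -> np.ndarray:
    """Check MaskRaster invariants and return a uint8 array in {0, 1}."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise FormatError(f"mask must be 2-D, got shape {arr.shape}")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise FormatError(f"mask must be strictly binary, found values {uniq[:8]}")
    return arr.astype(np.uint8)


def ensure_same_shape(*arrays: np.ndarray) -> None:
    shapes = {np.asarray(a).shape[-2:] for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


# ---------------------------------------------------------------------------
# displacement fields


@dataclasses.dataclass
class DisplacementField:
    """Dense backward-mapping displacement field in pixel units.

    ``dx`` displaces columns, ``dy`` rows; both are float32 H x W planes.
    """

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        self.dx = np.ascontiguousarray(self.dx, dtype=np.float32)
        self.dy = np.ascontiguousarray(self.dy, dtype=np.float32)
        if self.dx.ndim != 2 or self.dx.shape != self.dy.shape:
            raise ValueError(
                f"field planes must be 2-D and congruent, got {self.dx.shape} / {self.dy.shape}"
            )
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dx.shape

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "DisplacementField":
        return cls(np.zeros(shape, np.float32), np.zeros(shape, np.float32))

    @classmethod
    def from_stack(cls, planes: np.ndarray) -> "DisplacementField":
        """Build from a (2, H, W) stack ordered (dx, dy)."""
        planes = np.asarray(planes)
        if planes.ndim != 3 or planes.shape[0] != 2:
            raise ValueError(f"expected a (2, H, W) stack, got {planes.shape}")
        return cls(planes[0], planes[1])

    def as_stack(self) -> np.ndarray:
        return np.stack([self.dx, self.dy])

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx.astype(np.float64), self.dy.astype(np.float64))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DisplacementField):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.dx, other.dx)
            and np.array_equal(self.dy, other.dy)
        )


# ---------------------------------------------------------------------------
# raster I/O


def read_raster(path: str | Path, kind: str = "image") -> np.ndarray:
    """Read a single-channel 8/16-bit PNG or TIFF.

    Intensities are rescaled by the maximum representable value of the file's
    dtype to [0, 1]; ``kind="mask"`` then binarizes at > 0.5.
    """
    path = Path(path)
    if kind not in ("image", "mask"):
        raise ValueError(f"kind must be 'image' or 'mask', got {kind!r}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # unreadable file, whatever the backend raises
        raise FormatError(f"cannot read raster {path}: {exc}") from exc
    if raw.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel raster, got shape {raw.shape}")
    if raw.dtype == np.uint8:
        scale = 255.0
    elif raw.dtype == np.uint16:
        scale = 65535.0
    else:
        raise FormatError(f"{path}: unsupported dtype {raw.dtype}, expected uint8/uint16")
    arr = raw.astype(np.float64) / scale
    if kind == "mask":
        return (arr > 0.5).astype(np.uint8)
    return arr


def write_raster(path: str | Path, pixels: np.ndarray, bit_depth: int = 8) -> None:
    """Write a raster or mask as a single-channel PNG/TIFF at 8 or 16 bits."""
    path = Path(path)
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
    if bit_depth == 8:
        out = np.round(np.clip(arr, 0, 1) * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(np.clip(arr, 0, 1) * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, out)


# ---------------------------------------------------------------------------
# field container


def write_field(path: str | Path, field: DisplacementField) -> Path:
    """Serialize a field to the documented two-plane float32 container."""
    path = Path(path)
    h, w = field.shape
    with open(path, "wb") as fh:
        fh.write(FIELD_MAGIC)
        fh.write(struct.pack("<II", h, w))
        fh.write(field.dx.astype("<f4").tobytes())
        fh.write(field.dy.astype("<f4").tobytes())
    return path


def read_field(path: str | Path) -> DisplacementField:
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 12 or data[:4] != FIELD_MAGIC:
        raise FormatError(f"{path}: not a displacement-field container")
    h, w = struct.unpack("<II", data[4:12])
    expected = 12 + 2 * 4 * h * w
    if len(data) != expected:
        raise FormatError(f"{path}: truncated field container ({len(data)} != {expected} bytes)")
    planes = np.frombuffer(data[12:], dtype="<f4").reshape(2, h, w)
    return DisplacementField(planes[0].copy(), planes[1].copy())


# ---------------------------------------------------------------------------
# metric reports

METRIC_COLUMNS = ("dsc", "hd", "assd", "msd")
REPORT_COLUMNS = ("source", "target") + METRIC_COLUMNS


@dataclasses.dataclass
class MetricsReport:
    """Per-pair registration metrics plus aggregate statistics.

    ``rows`` is a DataFrame with columns (source, target, dsc, hd, assd, msd);
    distance columns may be NaN for pairs flagged as degenerate (an empty
    mask); flagged rows are excluded from aggregates.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.rows.columns) != list(REPORT_COLUMNS):
            self.rows = self.rows.loc[:, list(REPORT_COLUMNS)]
        if len(self.rows) == 0:
            raise ValueError("a MetricsReport needs at least one row")
        dsc = self.rows["dsc"].to_numpy(dtype=float)
        if np.nanmin(dsc) < 0 or np.nanmax(dsc) > 1:
            raise ValueError("dsc values must lie in [0, 1]")
        for col in ("hd", "assd", "msd"):
            vals = self.rows[col].to_numpy(dtype=float)
            if np.nanmin(vals) < 0:
                raise ValueError(f"{col} values must be >= 0")

    def aggregates(self) -> dict[str, dict[str, float]]:
        """mean/SD/min/max per metric over non-flagged rows (ddof=1 SD)."""
        out: dict[str, dict[str, float]] = {}
        for col in METRIC_COLUMNS:
            vals = self.rows[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            out[col] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
                "n": int(len(vals)),
            }
        return out

    def summary(self) -> str:
        """Human-readable 'mean (min-max) ± SD' lines, one per metric."""
        agg = self.aggregates()
        lines = []
        for col in METRIC_COLUMNS:
            a = agg[col]
            lines.append(
                f"{col.upper():>4}: {a['mean']:.3f} ({a['min']:.3f}-{a['max']:.3f}) "
                f"± {a['sd']:.3f}  [n={a['n']}]"
            )
        return "\n".join(lines)


def write_report(path: str | Path, report: MetricsReport) -> tuple[Path, Path]:
    """Write per-pair rows as CSV and aggregates as a sibling JSON file."""
    path = Path(path)
    report.rows.to_csv(path, index=False)
    json_path = path.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(report.aggregates(), fh, indent=2)
    return path, json_path


def read_report(path: str | Path) -> MetricsReport:
    rows = pd.read_csv(path)
    return MetricsReport(rows)


# ---------------------------------------------------------------------------
# sequence manifests


def write_manifest(path: str | Path, entries: list[dict], meta: dict | None = None) -> Path:
    """Write a JSON sequence manifest listing frame/mask/field files in order."""
    path = Path(path)
    payload = {"meta": meta or {}, "frames": entries}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path


def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read manifest {path}: {exc}") from exc
    if "frames" not in payload:
        raise FormatError(f"{path}: manifest lacks a 'frames' list")
    return payload
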