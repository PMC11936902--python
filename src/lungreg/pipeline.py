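"""Stage-complete inference: segmentation -> extraction -> registration.

``register_pair`` runs the whole three-stage pipeline on one frame pair;
``register_sequence`` applies it across a dynamic sequence, either over
all ordered pairs (the quantitative-evaluation protocol) or from one
reference frame to every other frame.  Frames whose size differs from the
model's training size are resized for inference; masks and fields are
mapped back to native resolution on output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

from .errors import PipelineError
from .extraction import binarize_mask, extract_lung_field
from .io_formats import DisplacementField, MetricsReport, write_field, write_raster
from .metrics import evaluate_pairs
from .networks import Segmenter, VectorCNN
from .warper import warp


@dataclasses.dataclass
class RegistrationResult:
    source_index: int
    target_index: int
    registered_lungfield: np.ndarray
    field: DisplacementField
    registered_mask: np.ndarray
    target_lungfield: np.ndarray
    target_mask: np.ndarray


def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape == (size, size):
        return img
    return np.clip(
        sktransform.resize(img, (size, size), order=1, preserve_range=True, anti_aliasing=True),
        0.0, 1.0,
    )


def _upscale_field(field: DisplacementField, shape: tuple[int, int]) -> DisplacementField:
    if field.shape == shape:
        return field
    ry = shape[0] / field.shape[0]
    rx = shape[1] / field.shape[1]
    dx = sktransform.resize(field.dx, shape, order=1, preserve_range=True) * rx
    dy = sktransform.resize(field.dy, shape, order=1, preserve_range=True) * ry
    return DisplacementField(dx.astype(np.float32), dy.astype(np.float32))


def register_pair(
    source: np.ndarray,
    target: np.ndarray,
    seg_model: Segmenter,
    reg_model: VectorCNN,
    threshold: float = 0.5,
) -> tuple[np.ndarray, DisplacementField, np.ndarray]:
    """Segment both frames, extract both lung fields, predict the field on
    the lung-field pair, warp the source lung field and mask.

    Returns (registered lung field, field, registered mask), all at the
    native frame resolution.
    """
    if source.shape != target.shape:
        raise ValueError(f"shape mismatch: {source.shape} vs {target.shape}")
    size = seg_model.cfg.image_size
    src = _resize_image(np.asarray(source, np.float64), size)
    tgt = _resize_image(np.asarray(target, np.float64), size)

    masks = []
    for name, img in (("source", src), ("target", tgt)):
        mask = binarize_mask(seg_model.predict_proba(img), threshold)
        if mask.sum() == 0:
            raise PipelineError(f"segmentation stage produced an empty mask for the {name} frame")
        masks.append(mask)
    src_mask, tgt_mask = masks
    src_lf = extract_lung_field(src, src_mask)
    tgt_lf = extract_lung_field(tgt, tgt_mask)

    field = reg_model.predict_field(src_lf, tgt_lf)
    field = _upscale_field(field, source.shape)
    native_src_mask = (
        src_mask if source.shape == (size, size)
        else (sktransform.resize(src_mask.astype(float), source.shape, order=0,
                                 preserve_range=True) > 0.5).astype(np.uint8)
    )
    native_src_lf = extract_lung_field(np.asarray(source, np.float64), native_src_mask)
    registered_lf = warp(native_src_lf, field)
    registered_mask = warp(native_src_mask, field, "nearest")
    if registered_mask.sum() == 0:
        raise PipelineError("registration stage warped the source mask to empty")
    return registered_lf, field, registered_mask


def register_sequence(
    frames: list[np.ndarray],
    seg_model: Segmenter,
    reg_model: VectorCNN,
    mode: str = "all_pairs",
    ref_index: int = 0,
    threshold: float = 0.5,
    msd_scale: float = 255.0,
    out=None,
) -> tuple[list[RegistrationResult], MetricsReport]:
    """Register a dynamic sequence and score every registration.

    ``mode="all_pairs"`` registers every ordered pair (n^2 - n of them);
    ``mode="to_reference"`` registers the reference frame to every other
    frame (n - 1 registrations).  The report compares each registered mask
    and lung field to its target.
    """
    from .training import enumerate_ordered_pairs

    if len(frames) < 2:
        raise ValueError("need at least two frames")
    if mode == "all_pairs":
        _, it = enumerate_ordered_pairs(len(frames))
        pairs = list(it)
    elif mode == "to_reference":
        if not 0 <= ref_index < len(frames):
            raise ValueError(f"reference index {ref_index} out of range")
        pairs = [(ref_index, j) for j in range(len(frames)) if j != ref_index]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    size = seg_model.cfg.image_size
    seg_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def segmented(k: int):
        if k not in seg_cache:
            img = _resize_image(np.asarray(frames[k], np.float64), size)
            mask = binarize_mask(seg_model.predict_proba(img), threshold)
            if mask.sum() == 0:
                raise PipelineError(f"segmentation stage produced an empty mask for frame {k}")
            seg_cache[k] = (img, mask)
        return seg_cache[k]

    results: list[RegistrationResult] = []
    metric_rows = []
    for i, j in pairs:
        src_img, src_mask = segmented(i)
        tgt_img, tgt_mask = segmented(j)
        src_lf = extract_lung_field(src_img, src_mask)
        tgt_lf = extract_lung_field(tgt_img, tgt_mask)
        field = reg_model.predict_field(src_lf, tgt_lf)
        reg_lf = warp(src_lf, field)
        reg_mask = warp(src_mask, field, "nearest")
        results.append(RegistrationResult(i, j, reg_lf, field, reg_mask, tgt_lf, tgt_mask))
        metric_rows.append((i, j, tgt_mask, reg_mask, tgt_lf, reg_lf))
    report = evaluate_pairs(metric_rows, msd_scale=msd_scale)

    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        from .io_formats import write_report

        for r in results:
            stem = f"reg_{r.source_index:03d}_to_{r.target_index:03d}"
            write_raster(out / f"{stem}.png", r.registered_lungfield)
            write_raster(out / f"{stem}_mask.png", r.registered_mask.astype(np.float64))
            write_field(out / f"{stem}.field", r.field)
        write_report(out / "report.csv", report)
    return results, report
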