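"""Resampling of rasters under dense displacement fields (evaluation path).

The warp is a backward map: the output at pixel p samples the input at
p + (dx, dy).  Images use bilinear interpolation, masks nearest-neighbour
(so they stay strictly binary).  With ``"zeros"`` padding an out-of-bounds
corner contributes 0 and partially-outside samples blend towards 0; with
``"border"`` coordinates are clamped to the edge.  The differentiable
counterpart used during training (:func:`lungreg.nn.grid_sample`) shares
these conventions and agrees numerically on the forward pass.
"""

from __future__ import annotations

import numpy as np

from .errors import ContractError
from .io_formats import DisplacementField, ensure_same_shape


def _bilinear(arr: np.ndarray, py: np.ndarray, px: np.ndarray, padding: str) -> np.ndarray:
    h, w = arr.shape
    if padding == "border":
        py = np.clip(py, 0.0, h - 1.0)
        px = np.clip(px, 0.0, w - 1.0)
    y0 = np.floor(py)
    x0 = np.floor(px)
    wy = py - y0
    wx = px - x0

    def corner(yy, xx):
        valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        yc = np.clip(yy, 0, h - 1).astype(np.intp)
        xc = np.clip(xx, 0, w - 1).astype(np.intp)
        return arr[yc, xc] * valid

    return (
        corner(y0, x0) * (1 - wy) * (1 - wx)
        + corner(y0, x0 + 1) * (1 - wy) * wx
        + corner(y0 + 1, x0) * wy * (1 - wx)
        + corner(y0 + 1, x0 + 1) * wy * wx
    )


def _nearest(arr: np.ndarray, py: np.ndarray, px: np.ndarray, padding: str) -> np.ndarray:
    h, w = arr.shape
    yr = np.round(py)
    xr = np.round(px)
    if padding == "border":
        yr = np.clip(yr, 0, h - 1)
        xr = np.clip(xr, 0, w - 1)
    valid = (yr >= 0) & (yr < h) & (xr >= 0) & (xr < w)
    yc = np.clip(yr, 0, h - 1).astype(np.intp)
    xc = np.clip(xr, 0, w - 1).astype(np.intp)
    return arr[yc, xc] * valid


def warp(
    input_raster: np.ndarray,
    field: DisplacementField,
    interpolation: str = "bilinear",
    padding: str = "zeros",
) -> np.ndarray:
    """Warp ``input_raster`` by ``field``: output(p) = input(p + field(p)).

    Parameters
    ----------
    input_raster
        H x W image (float, in [0, 1]) or mask (integer {0, 1}).
    field
        Backward-mapping displacement in pixel units.
    interpolation
        ``"bilinear"`` for images, ``"nearest"`` for masks.  Bilinear
        sampling of a binary mask is rejected: it would produce non-binary
        values on the evaluation path.
    padding
        ``"zeros"`` (out-of-bounds samples are 0) or ``"border"`` (clamp to
        the edge value).
    """
    arr = np.asarray(input_raster)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {arr.shape}")
    ensure_same_shape(arr, field.dx)
    if interpolation not in ("bilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if padding not in ("zeros", "border"):
        raise ValueError(f"unknown padding {padding!r}")

    is_mask = np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool
    if is_mask and interpolation == "bilinear":
        raise ContractError("bilinear interpolation on a binary mask; use 'nearest'")

    h, w = arr.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    py = rows + field.dy.astype(np.float64)
    px = cols + field.dx.astype(np.float64)
    data = arr.astype(np.float64)
    if interpolation == "bilinear":
        out = _bilinear(data, py, px, padding)
    else:
        out = _nearest(data, py, px, padding)
    if is_mask:
        return (out > 0.5).astype(np.uint8)
    return out


def warp_mask_soft(mask: np.ndarray, field: DisplacementField, padding: str = "zeros") -> np.ndarray:
    """Bilinearly warp a mask into a *soft* (fractional) raster.

    This mirrors what the training path does before the overlap and latent
    penalties are applied; evaluation normally uses the hard nearest path.
    """
    return warp(np.asarray(mask, dtype=np.float64), field, "bilinear", padding)
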