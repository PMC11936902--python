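"""Registration evaluation metrics: DSC, HD, ASSD, MSD.

DSC is the overlap of the two foreground sets.  HD and ASSD operate on
*boundary* pixel sets (foreground pixels with at least one 4-neighbour of
background, the outside of the image counting as background) using exact
Euclidean distance transforms; a flag switches HD to full-region sets.
MSD is the mean squared intensity difference, computed on [0, 1]
intensities and reported after multiplying by a configurable intensity
scale (255 by default in the report path, for comparability with 8-bit
conventions).

Empty-mask policy: DSC of two empty masks is 1.0 by convention; the
surface distances are undefined for an empty mask — at the single-pair
level that raises, while :func:`evaluate_pairs` flags the row with NaN,
logs a warning and excludes it from the aggregates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io_formats import MetricsReport, ensure_same_shape, validate_mask, validate_raster


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|); 1.0 if both empty."""
    ma = validate_mask(a)
    mb = validate_mask(b)
    ensure_same_shape(ma, mb)
    sa = int(ma.sum())
    sb = int(mb.sum())
    if sa + sb == 0:
        return 1.0
    inter = int((ma & mb).sum())
    return 2.0 * inter / (sa + sb)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean map of foreground pixels with a 4-neighbour background pixel
    (image border counts as background)."""
    m = validate_mask(mask).astype(bool)
    eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(2, 1),
                                    border_value=0)
    return m & ~eroded


def _point_sets(a: np.ndarray, b: np.ndarray, mode: str):
    ma = validate_mask(a)
    mb = validate_mask(b)
    ensure_same_shape(ma, mb)
    if ma.sum() == 0 or mb.sum() == 0:
        raise ValueError("surface distances are undefined for an empty mask")
    if mode == "surface":
        return boundary_pixels(ma), boundary_pixels(mb)
    if mode == "region":
        return ma.astype(bool), mb.astype(bool)
    raise ValueError(f"unknown mode {mode!r}")


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point of src to the nearest point of dst."""
    dt = ndimage.distance_transform_edt(~dst)
    return dt[src]


def hausdorff(a: np.ndarray, b: np.ndarray, mode: str = "surface") -> float:
    """Symmetric Hausdorff distance: the larger of the two directed maxima."""
    pa, pb = _point_sets(a, b, mode)
    return float(max(_directed_distances(pa, pb).max(), _directed_distances(pb, pa).max()))


def assd(a: np.ndarray, b: np.ndarray) -> float:
    """Average symmetric surface distance over both boundary sets."""
    pa, pb = _point_sets(a, b, "surface")
    d_ab = _directed_distances(pa, pb)
    d_ba = _directed_distances(pb, pa)
    return float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size))


def msd(a: np.ndarray, b: np.ndarray, scale: float = 1.0) -> float:
    """Mean squared intensity distance, on intensities times ``scale``."""
    ia = validate_raster(a)
    ib = validate_raster(b)
    ensure_same_shape(ia, ib)
    diff = (ia - ib) * float(scale)
    return float(np.mean(diff * diff))


def evaluate_pairs(
    pairs: list[tuple],
    msd_scale: float = 255.0,
    hd_mode: str = "surface",
) -> MetricsReport:
    """Score a list of (fixed mask, moving mask, fixed image, moving image)
    tuples; 6-tuples may carry leading (source id, target id).

    Returns per-pair rows plus aggregates; degenerate pairs (an empty
    mask) get NaN distances, a warning, and are excluded from aggregates.
    """
    if not pairs:
        raise ValueError("evaluate_pairs needs at least one pair")
    rows = []
    for k, pair in enumerate(pairs):
        if len(pair) == 6:
            src_id, tgt_id, fixed_mask, moving_mask, fixed_img, moving_img = pair
        elif len(pair) == 4:
            fixed_mask, moving_mask, fixed_img, moving_img = pair
            src_id, tgt_id = k, k
        else:
            raise ValueError("each pair must be a 4- or 6-tuple")
        d = dsc(fixed_mask, moving_mask)
        m = msd(fixed_img, moving_img, scale=msd_scale)
        try:
            h = hausdorff(fixed_mask, moving_mask, mode=hd_mode)
            s = assd(fixed_mask, moving_mask)
        except ValueError:
            warnings.warn(
                f"pair ({src_id}, {tgt_id}): empty mask, distances flagged NaN and "
                "excluded from aggregates",
                stacklevel=2,
            )
            h = s = float("nan")
        rows.append((src_id, tgt_id, d, h, s, m))
    frame = pd.DataFrame(rows, columns=["source", "target", "dsc", "hd", "assd", "msd"])
    return MetricsReport(frame)


def paired_significance(arm_a, arm_b, test: str = "wilcoxon") -> float:
    """Two-sided paired p-value between two metric columns.

    Default is the Wilcoxon signed-rank test (no normality assumption on
    the paired differences); ``test="ttest"`` uses the paired t-test.
    Identical columns return p = 1.0 by convention.
    """
    a = np.asarray(arm_a, dtype=np.float64)
    b = np.asarray(arm_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("arms must be equal-length 1-D columns with n >= 2")
    if np.array_equal(a, b):
        return 1.0
    if test == "wilcoxon":
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    if test == "ttest":
        return float(stats.ttest_rel(a, b).pvalue)
    raise ValueError(f"unknown test {test!r}")
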