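"""Lung-field extraction: binarize segmenter output, multiply into the image.

The lung field is cut out of the radiograph by setting every lung pixel of
the mask to 1 and every non-lung pixel to 0, then multiplying mask and
image pixel-wise — the extracted image keeps the original grayscale inside
the lung field and is exactly zero outside it.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .io_formats import ensure_same_shape, validate_mask, validate_raster


def binarize_mask(raw: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability/label raster into a binary mask.

    The tie rule is strict: pixels exactly equal to the threshold map to 0.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    arr = validate_raster(raw)
    return (arr > threshold).astype(np.uint8)


def extract_lung_field(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pixel-wise product of image and binary mask."""
    img = validate_raster(image)
    msk = validate_mask(mask)
    ensure_same_shape(img, msk)
    return img * msk


def keep_largest_components(mask: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Optional cleanup for noisy segmenters: keep the n largest connected
    components (default two, one per lung).  Not applied by default."""
    msk = validate_mask(mask)
    labels = measure.label(msk, connectivity=2)
    if labels.max() <= n_components:
        return msk
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = np.argsort(areas)[::-1][:n_components]
    return np.isin(labels, keep).astype(np.uint8)
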