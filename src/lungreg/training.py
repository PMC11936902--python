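"""Three-step training of the registration network, and the ablation harness.

The deformation predictor is trained in three cascaded steps on a corpus
of static chest images with lung masks:

1. *initial* — all ordered pairs of full images (n^2 - n of them,
   uniformly subsampled per epoch at desk scale) with the full composite
   loss, producing model V1;
2. *enhanced* — pairs (image -> affine-transformed image), one fresh
   affine draw per image per epoch, producing V2;
3. *final* — the same pairing scheme on *extracted lung fields*
   (image x mask), producing V3.

The affine transform applied to an image and to its mask is always the
same draw, so the overlap and latent penalties see geometrically
consistent targets.  The anatomical-constraint encoder is trained first
and stays frozen through all three steps.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from skimage import transform as sktransform

from .errors import ConfigurationError
from .io_formats import MetricsReport, validate_mask, validate_raster
from .losses import LossWeights, composite_loss
from .networks import Autoencoder, NetConfig, Segmenter, VectorCNN, build_vectorcnn
from .warper import warp

# ---------------------------------------------------------------------------
# affine augmentation


@dataclasses.dataclass
class AffineParams:
    """One affine augmentation draw: rotation/shear in degrees, isotropic
    scale factor, translation as a fraction of the image side (x, y)."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    translation_frac: tuple[float, float] = (0.0, 0.0)
    shear_deg: float = 0.0

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls()

    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0.0
            and self.scale == 1.0
            and self.translation_frac == (0.0, 0.0)
            and self.shear_deg == 0.0
        )


DEFAULT_AFFINE_RANGES: dict[str, tuple[float, float]] = {
    "rotation": (-5.0, 5.0),
    "scale": (0.95, 1.05),
    "translation": (-0.05, 0.05),
    "shear": (-3.0, 3.0),
}


def _affine_tform(params: AffineParams, shape: tuple[int, int]) -> sktransform.AffineTransform:
    """Forward transform about the image centre, in (x, y) = (col, row)."""
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    tx = params.translation_frac[0] * w
    ty = params.translation_frac[1] * h
    core = sktransform.AffineTransform(
        scale=params.scale,
        rotation=np.deg2rad(params.rotation_deg),
        shear=np.deg2rad(params.shear_deg),
    )
    to_origin = sktransform.SimilarityTransform(translation=(-cx, -cy))
    back = sktransform.SimilarityTransform(translation=(cx + tx, cy + ty))
    return to_origin + core + back


def make_affine_pair(
    image: np.ndarray, mask: np.ndarray, params: AffineParams
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the SAME affine transform to an image (bilinear) and its mask
    (nearest, re-binarized)."""
    img = validate_raster(image)
    msk = validate_mask(mask)
    if img.shape != msk.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {msk.shape}")
    if params.is_identity():
        return img.copy(), msk.copy()
    tform = _affine_tform(params, img.shape)
    out_img = sktransform.warp(img, tform.inverse, order=1, mode="constant", cval=0.0,
                               preserve_range=True)
    out_msk = sktransform.warp(msk.astype(np.float64), tform.inverse, order=0,
                               mode="constant", cval=0.0, preserve_range=True)
    return np.clip(out_img, 0.0, 1.0), (out_msk > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# pair enumeration


def enumerate_ordered_pairs(n_items: int):
    """All ordered pairs (i, j) with i != j, in deterministic row-major
    order.  Returns (count, iterator); count = n^2 - n."""
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    count = n_items * n_items - n_items

    def gen():
        for i in range(n_items):
            for j in range(n_items):
                if i != j:
                    yield (i, j)

    return count, gen()


# ---------------------------------------------------------------------------
# step configuration and the shared training loop


@dataclasses.dataclass
class TrainStepConfig:
    """Settings for one training step (t = 1, 2 or 3)."""

    step: int = 1
    epochs: int = 4
    batch_size: int = 8
    learning_rate: float = 2e-3
    pairs_per_epoch: int = 64
    affine_ranges: dict[str, tuple[float, float]] | None = None
    weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    clip_norm: float | None = 0.5
    seed: int = 0
    include_reversed: bool = False

    def validate(self) -> "TrainStepConfig":
        if self.step not in (1, 2, 3):
            raise ConfigurationError(f"step must be 1, 2 or 3, got {self.step}")
        if self.pairs_per_epoch < 1 or self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("epochs, batch_size and pairs_per_epoch must be >= 1")
        self.weights.validate()
        return self


def _stack(images: list[np.ndarray]) -> np.ndarray:
    return np.stack([np.asarray(im, np.float32) for im in images])[..., None]


def _run_batches(model, opt, encoder, cfg, batches, log):
    for src, tgt, smask, tmask in batches:
        field = model(src, tgt)
        loss = composite_loss(src, tgt, smask, tmask, field, cfg.weights, encoder).total
        opt.zero_grad()
        for p in encoder.parameters():
            p.grad = None
        loss.backward()
        opt.step()
        log.append(float(loss.data))
    return log


def train_step1(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    encoder: Autoencoder,
    cfg: TrainStepConfig,
    model: VectorCNN | None = None,
    net_config: NetConfig | None = None,
) -> tuple[VectorCNN, list[float]]:
    """Initial training on ordered pairs of full images -> model V1.

    The full ordered-pair set has n^2 - n members; each epoch draws
    ``pairs_per_epoch`` of them uniformly without replacement.
    """
    from . import nn

    cfg = dataclasses.replace(cfg, step=1).validate()
    if len(images) < 2 or len(images) != len(masks):
        raise ValueError("need >= 2 images with matching masks")
    if model is None:
        size = images[0].shape[0]
        model = build_vectorcnn(net_config or NetConfig(image_size=size, depth=3, seed=cfg.seed))
    xs = _stack(images)
    ms = _stack(masks)
    count, it = enumerate_ordered_pairs(len(images))
    all_pairs = np.array(list(it))
    rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 1])
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate, clip_norm=cfg.clip_norm)
    log: list[float] = []
    for _ in range(cfg.epochs):
        take = min(cfg.pairs_per_epoch, count)
        sel = all_pairs[rng.choice(count, size=take, replace=False)]
        batches = (
            (xs[chunk[:, 0]], xs[chunk[:, 1]], ms[chunk[:, 0]], ms[chunk[:, 1]])
            for chunk in np.array_split(sel, math.ceil(take / cfg.batch_size))
        )
        _run_batches(model, opt, encoder, cfg, batches, log)
    return model, log


def _train_affine_step(
    model: VectorCNN,
    images: list[np.ndarray],
    masks: list[np.ndarray],
    affine_ranges: dict | None,
    encoder: Autoencoder,
    cfg: TrainStepConfig,
    step: int,
) -> tuple[VectorCNN, list[float]]:
    from . import nn
    from .phantom import sample_affine  # deferred: phantom imports AffineParams from here

    cfg = dataclasses.replace(cfg, step=step).validate()
    if len(images) < 2 or len(images) != len(masks):
        raise ValueError("need >= 2 images with matching masks")
    ranges = dict(DEFAULT_AFFINE_RANGES)
    if affine_ranges:
        ranges.update(affine_ranges)
    rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, step])
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate, clip_norm=cfg.clip_norm)
    log: list[float] = []
    n = len(images)
    for _ in range(cfg.epochs):
        # one fresh affine draw per image per epoch; image and mask share it
        aff = [
            make_affine_pair(
                images[i], masks[i], sample_affine(int(rng.integers(2**31)), **ranges)
            )
            for i in range(n)
        ]
        srcs = list(images) + ([a[0] for a in aff] if cfg.include_reversed else [])
        smsk = list(masks) + ([a[1] for a in aff] if cfg.include_reversed else [])
        tgts = [a[0] for a in aff] + (list(images) if cfg.include_reversed else [])
        tmsk = [a[1] for a in aff] + (list(masks) if cfg.include_reversed else [])
        xs, axs = _stack(srcs), _stack(tgts)
        ms, ams = _stack(smsk), _stack(tmsk)
        order = rng.permutation(len(srcs))
        batches = (
            (xs[chunk], axs[chunk], ms[chunk], ams[chunk])
            for chunk in np.array_split(order, math.ceil(len(srcs) / cfg.batch_size))
        )
        _run_batches(model, opt, encoder, cfg, batches, log)
    return model, log


def train_step2(
    model: VectorCNN,
    images: list[np.ndarray],
    masks: list[np.ndarray],
    affine_ranges: dict | None,
    encoder: Autoencoder,
    cfg: TrainStepConfig,
) -> tuple[VectorCNN, list[float]]:
    """Enhanced training on (image -> affine image) pairs -> model V2."""
    return _train_affine_step(model, images, masks, affine_ranges, encoder, cfg, step=2)


def train_step3(
    model: VectorCNN,
    lungfield_images: list[np.ndarray],
    masks: list[np.ndarray],
    affine_ranges: dict | None,
    encoder: Autoencoder,
    cfg: TrainStepConfig,
) -> tuple[VectorCNN, list[float]]:
    """Final training on extracted lung fields -> model V3.

    Inputs are expected to be zero outside the mask support (the output of
    the extraction stage); a nonzero background only warns.
    """
    for k, (img, msk) in enumerate(zip(lungfield_images, masks)):
        outside = np.asarray(img)[np.asarray(msk) == 0]
        if outside.size and float(np.abs(outside).max()) > 1e-6:
            warnings.warn(
                f"lung-field image {k} has nonzero background "
                f"(max {float(np.abs(outside).max()):.3g}); expected extracted inputs",
                stacklevel=2,
            )
    return _train_affine_step(model, lungfield_images, masks, affine_ranges, encoder, cfg, step=3)


# ---------------------------------------------------------------------------
# ablation harness


def run_ablation(
    sequence,
    seg_model: Segmenter | None,
    models: dict[str, VectorCNN],
    out=None,
    threshold: float = 0.5,
    msd_scale: float = 255.0,
) -> dict[str, MetricsReport]:
    """Evaluate every ordered frame pair of a sequence under each arm.

    Arms: ``baseline`` (unregistered full frames), ``baseline_lungfield``
    (same masks, MSD on extracted lung fields), ``v1``/``v2`` (registration
    of full frames), ``v3`` (registration of extracted lung fields).  Masks
    come from the segmenter when one is given, else from the sequence's
    ground truth.  Returns one MetricsReport per arm; with ``out`` set,
    CSV + JSON reports are written there.
    """
    from .extraction import binarize_mask, extract_lung_field
    from .metrics import evaluate_pairs

    for key in ("v1", "v2", "v3"):
        if key not in models:
            raise ConfigurationError(f"missing model {key!r} for the ablation")
    frames = list(sequence.frames)
    if seg_model is not None:
        masks = [binarize_mask(seg_model.predict_proba(f), threshold) for f in frames]
    else:
        masks = list(sequence.masks)
    fields_cache: dict[tuple[str, int, int], object] = {}
    lungfields = [extract_lung_field(f, m) for f, m in zip(frames, masks)]
    count, pair_iter = enumerate_ordered_pairs(len(frames))
    pairs = list(pair_iter)

    def rows_for(arm: str):
        rows = []
        for i, j in pairs:
            if arm == "baseline":
                rows.append((i, j, masks[j], masks[i], frames[j], frames[i]))
            elif arm == "baseline_lungfield":
                rows.append((i, j, masks[j], masks[i], lungfields[j], lungfields[i]))
            elif arm in ("v1", "v2"):
                field = models[arm].predict_field(frames[i], frames[j])
                rows.append(
                    (i, j, masks[j], warp(masks[i], field, "nearest"),
                     frames[j], warp(frames[i], field)))
            elif arm == "v3":
                field = fields_cache.get(("v3", i, j))
                if field is None:
                    field = models["v3"].predict_field(lungfields[i], lungfields[j])
                    fields_cache[("v3", i, j)] = field
                rows.append(
                    (i, j, masks[j], warp(masks[i], field, "nearest"),
                     lungfields[j], warp(lungfields[i], field)))
        return rows

    reports = {}
    for arm in ("baseline", "baseline_lungfield", "v1", "v2", "v3"):
        reports[arm] = evaluate_pairs(rows_for(arm), msd_scale=msd_scale)
    if out is not None:
        from pathlib import Path

        from .io_formats import write_report

        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        for arm, rep in reports.items():
            write_report(out / f"ablation_{arm}.csv", rep)
    return reports
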