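"""The three learnable components and their builders.

* ``build_segmenter`` — a U-Net-style encoder-decoder with skip
  connections mapping a radiograph to a per-pixel lung probability map
  (stage I of the pipeline).
* ``build_vectorcnn`` — the deformation predictor: the same encoder-decoder
  family, fed the source and target images as two channels and emitting a
  two-plane displacement field.  Its final layer is zero-initialised so a
  fresh model starts at the identity transform.
* ``build_autoencoder`` — a denoising autoencoder over binary lung masks,
  *without* skip connections so the n x n single-channel bottleneck code is
  informative; its frozen encoder provides the anatomical latent penalty
  during registration training.

All models are plain numpy/autodiff modules; they run on (N, H, W, C)
float32 batches and are reproducible under (seed, config, data).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .errors import ConfigurationError
from .io_formats import DisplacementField

# Default Adam settings shared by all trainers in this package.  The small
# desk-scale models train in minutes on one CPU core at this rate.
DEFAULT_LR = 2e-3
DEFAULT_BATCH = 8


@dataclasses.dataclass
class NetConfig:
    """Architecture settings shared by the three model builders.

    ``depth`` is the number of 2x downsamplings; the autoencoder code grid
    is ``n = image_size / 2**depth`` per side.  ``image_size`` must be
    divisible by ``2**depth``.
    """

    image_size: int = 96
    base_channels: int = 8
    depth: int = 4
    seed: int = 0

    def validate(self) -> "NetConfig":
        if self.image_size % (2**self.depth) != 0:
            raise ConfigurationError(
                f"image_size {self.image_size} is not divisible by 2**depth={2**self.depth}"
            )
        if self.base_channels < 1 or self.depth < 1:
            raise ConfigurationError("base_channels and depth must be >= 1")
        return self

    @property
    def latent_n(self) -> int:
        return self.image_size // (2**self.depth)


def _channels(cfg: NetConfig, level: int, cap: int = 32) -> int:
    return min(cfg.base_channels * (2**level), cap)


class _ConvBlock(nn.Module):
    def __init__(self, in_ch, out_ch, rng):
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, rng)

    def __call__(self, x):
        return self.c2(self.c1(x).leaky_relu()).leaky_relu()


class UNet(nn.Module):
    """Encoder-decoder with skip connections; configurable head.

    With ``global_head=True`` a second head global-average-pools the
    bottleneck features into one ``out_ch``-vector that is broadcast-added
    to the dense output — a global pathway that lets a deformation
    predictor carry bulk translation separately from local deformation.
    """

    def __init__(self, cfg: NetConfig, in_ch: int, out_ch: int, final: str,
                 zero_init_final: bool = False, global_head: bool = False):
        cfg.validate()
        self.cfg = cfg
        self.final = final
        rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, in_ch, out_ch])
        self.enc = [
            _ConvBlock(in_ch if i == 0 else _channels(cfg, i - 1), _channels(cfg, i), rng)
            for i in range(cfg.depth)
        ]
        self.bottleneck = _ConvBlock(_channels(cfg, cfg.depth - 1), _channels(cfg, cfg.depth), rng)
        self.dec = [
            _ConvBlock(_channels(cfg, i) + _channels(cfg, i + 1), _channels(cfg, i), rng)
            for i in reversed(range(cfg.depth))
        ]
        self.head = nn.Conv2d(_channels(cfg, 0), out_ch, 1, rng, zero_init=zero_init_final)
        self.global_head = (
            nn.Conv2d(_channels(cfg, cfg.depth), out_ch, 1, rng, zero_init=zero_init_final)
            if global_head
            else None
        )

    def __call__(self, x) -> nn.Tensor:
        x = nn.as_tensor(x)
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = nn.avg_pool2(x)
        x = self.bottleneck(x)
        bottleneck = x
        for block, skip in zip(self.dec, reversed(skips)):
            x = block(nn.concat([skip, nn.upsample2(x)], axis=3))
        x = self.head(x)
        if self.global_head is not None:
            x = x + self.global_head(bottleneck.mean(axis=(1, 2), keepdims=True))
        if self.final == "sigmoid":
            x = x.sigmoid()
        return x


class Segmenter(nn.Module):
    """Radiograph -> lung-field probability map."""

    def __init__(self, cfg: NetConfig):
        self.net = UNet(cfg, in_ch=1, out_ch=1, final="sigmoid")
        self.cfg = cfg

    def __call__(self, batch) -> nn.Tensor:
        return self.net(batch)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Probability map for a single H x W image (inference, no grads)."""
        out = self.net(image[None, :, :, None].astype(np.float32))
        return out.data[0, :, :, 0].astype(np.float64)


class VectorCNN(nn.Module):
    """(source, target) -> dense displacement field.

    The zero-initialised head makes a fresh model predict the identity
    transform, the standard stabilisation for unsupervised registration.
    """

    def __init__(self, cfg: NetConfig):
        self.net = UNet(cfg, in_ch=2, out_ch=2, final="linear", zero_init_final=True,
                        global_head=True)
        self.cfg = cfg

    def __call__(self, source_batch, target_batch) -> nn.Tensor:
        src = nn.as_tensor(source_batch)
        tgt = nn.as_tensor(target_batch)
        return self.net(nn.concat([src, tgt], axis=3))

    def predict_field(self, source: np.ndarray, target: np.ndarray) -> DisplacementField:
        out = self(source[None, :, :, None].astype(np.float32), target[None, :, :, None].astype(np.float32))
        return DisplacementField(out.data[0, :, :, 0], out.data[0, :, :, 1])


class Autoencoder(nn.Module):
    """Denoising autoencoder over lung masks with an n x n latent grid."""

    def __init__(self, cfg: NetConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 0xAE])
        ch = [min(cfg.base_channels * (2**i), 32) for i in range(cfg.depth)]
        self.enc_convs = [
            nn.Conv2d(1 if i == 0 else ch[i - 1], ch[i], 3, rng) for i in range(cfg.depth)
        ]
        self.to_code = nn.Conv2d(ch[-1], 1, 1, rng)
        self.from_code = nn.Conv2d(1, ch[-1], 1, rng)
        self.dec_convs = [
            nn.Conv2d(ch[i], 1 if i == 0 else ch[i - 1], 3, rng)
            for i in reversed(range(cfg.depth))
        ]

    def encode(self, mask_batch) -> nn.Tensor:
        x = nn.as_tensor(mask_batch)
        for conv in self.enc_convs:
            x = nn.avg_pool2(conv(x).leaky_relu())
        return self.to_code(x)

    def decode(self, code: nn.Tensor) -> nn.Tensor:
        x = self.from_code(nn.as_tensor(code)).leaky_relu()
        for i, conv in enumerate(self.dec_convs):
            x = conv(nn.upsample2(x))
            if i < len(self.dec_convs) - 1:
                x = x.leaky_relu()
        return x.sigmoid()

    def __call__(self, mask_batch) -> nn.Tensor:
        return self.decode(self.encode(mask_batch))

    def encode_array(self, mask: np.ndarray) -> np.ndarray:
        """n x n latent code of a single H x W mask (inference)."""
        return self.encode(mask[None, :, :, None].astype(np.float32)).data[0, :, :, 0].copy()


def build_segmenter(config: NetConfig) -> Segmenter:
    return Segmenter(config.validate())


def build_vectorcnn(config: NetConfig) -> VectorCNN:
    return VectorCNN(config.validate())


def build_autoencoder(config: NetConfig) -> Autoencoder:
    return Autoencoder(config.validate())


# ---------------------------------------------------------------------------
# training of the two auxiliary models


def _bce(pred: nn.Tensor, target: np.ndarray, clip: float = 1e-6) -> nn.Tensor:
    p = pred.clip(clip, 1.0 - clip)
    t = nn.as_tensor(target)
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train_autoencoder(
    masks: list[np.ndarray],
    noise_rate: float = 0.05,
    epochs: int = 30,
    batch_size: int = DEFAULT_BATCH,
    lr: float = DEFAULT_LR,
    seed: int = 0,
    config: NetConfig | None = None,
) -> tuple[Autoencoder, list[float]]:
    """Train the anatomical-constraint autoencoder by denoising.

    Inputs are corrupted by independent pixel flips at ``noise_rate``; the
    model minimises binary cross-entropy against the clean mask.  Returns
    the model and the per-step loss log.
    """
    if len(masks) < 2:
        raise ValueError(f"need at least 2 masks, got {len(masks)}")
    size = masks[0].shape[0]
    cfg = config or NetConfig(image_size=size, seed=seed)
    model = Autoencoder(cfg)
    stack = np.stack([np.asarray(m, np.float32) for m in masks])[..., None]
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xD0])
    opt = nn.Adam(model.parameters(), lr=lr)
    log: list[float] = []
    for _ in range(epochs):
        for idx in _batches(len(masks), batch_size, rng):
            clean = stack[idx]
            noisy = clean.copy()
            if noise_rate > 0:
                flip = rng.random(clean.shape) < noise_rate
                noisy[flip] = 1.0 - noisy[flip]
            loss = _bce(model(noisy), clean)
            opt.zero_grad()
            loss.backward()
            opt.step()
            log.append(loss.item())
    return model, log


def train_segmenter(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    epochs: int = 30,
    batch_size: int = DEFAULT_BATCH,
    lr: float = DEFAULT_LR,
    seed: int = 0,
    config: NetConfig | None = None,
) -> tuple[Segmenter, list[float]]:
    """Train the stage-I lung-field segmenter with per-pixel BCE."""
    if len(images) != len(masks) or len(images) < 2:
        raise ValueError("need >= 2 image/mask pairs of equal count")
    size = images[0].shape[0]
    cfg = config or NetConfig(image_size=size, depth=3, seed=seed)
    model = Segmenter(cfg)
    xs = np.stack([np.asarray(im, np.float32) for im in images])[..., None]
    ys = np.stack([np.asarray(m, np.float32) for m in masks])[..., None]
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x5E])
    opt = nn.Adam(model.parameters(), lr=lr)
    log: list[float] = []
    for _ in range(epochs):
        for idx in _batches(len(images), batch_size, rng):
            loss = _bce(model(xs[idx]), ys[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            log.append(loss.item())
    return model, log


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, model: nn.Module) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(path, model: nn.Module) -> nn.Module:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
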