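"""Synthetic breathing-chest phantom with ground-truth deformation fields.

The phantom emulates a posteroanterior chest radiograph at desk scale: two
vertically elongated, super-elliptical bright lung fields on a darker
thoracic background, with rib-like horizontal bands inside the lungs and
additive Gaussian noise.  A breathing cycle is modelled as a
diaphragm-dominant vertical displacement that is zero at the lung apex and
grows towards the base, plus a small lateral expansion about the midline —
a smooth caricature of the non-rigid contraction/expansion of real lungs.

Every frame is rendered from one *material* pattern through an analytic
forward motion map F_phase(q) = q + f_phase(q).  Because frame 0 (phase 0)
is the reference, the dense field that warps frame k back onto frame 0
under the package's backward-mapping convention is simply f_phase_k
evaluated on the pixel grid; rendering inverts F by fixed-point iteration.
Identical (config, seed) always produce bit-identical sequences.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ConfigurationError
from .io_formats import DisplacementField
from .training import AffineParams


@dataclasses.dataclass
class PhantomConfig:
    """Generator settings; defaults give an 11-frame, 96 x 96 cycle.

    ``breathing_amplitude`` is the fraction of the lung height the
    diaphragm analogue descends at full inspiration (dimensionless);
    ``texture_strength`` scales the contrast of the rib-like bands;
    ``noise_sd`` is the SD of the additive Gaussian intensity noise.
    """

    image_size: int = 96
    n_frames: int = 11
    breathing_amplitude: float = 0.15
    texture_strength: float = 0.4
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> "PhantomConfig":
        if self.image_size < 32:
            raise ConfigurationError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_frames < 1:
            raise ConfigurationError(f"n_frames must be >= 1, got {self.n_frames}")
        if not 0.0 <= self.breathing_amplitude <= 0.3:
            raise ConfigurationError(
                f"breathing_amplitude must be in [0, 0.3], got {self.breathing_amplitude}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.texture_strength <= 1.0:
            raise ConfigurationError(
                f"texture_strength must be in [0, 1], got {self.texture_strength}"
            )
        return self


@dataclasses.dataclass
class PhantomSequence:
    """One breathing cycle: frames, masks and frame->frame-0 truth fields."""

    frames: list[np.ndarray]
    masks: list[np.ndarray]
    true_fields: list[DisplacementField]
    config: PhantomConfig

    def __post_init__(self) -> None:
        n = len(self.frames)
        if not (len(self.masks) == len(self.true_fields) == n):
            raise ValueError("frames, masks and true_fields must have equal lengths")
        area = float(self.frames[0].size)
        for k, mask in enumerate(self.masks):
            frac = float(mask.sum()) / area
            if not 0.05 < frac < 0.6:
                raise ValueError(
                    f"mask {k} foreground fraction {frac:.3f} outside (0.05, 0.6)"
                )

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# anatomy


@dataclasses.dataclass(frozen=True)
class _Anatomy:
    """Per-seed geometry of the two lungs and thorax, in pixel units."""

    size: int
    lung_cx: tuple[float, float]  # left, right lung centre columns
    lung_cy: float
    semi_a: tuple[float, float]  # horizontal semi-axes
    semi_b: tuple[float, float]  # vertical semi-axes
    exponent: float
    rib_period: float
    rib_phase: float
    # vascular-like broadband texture: random-orientation sinusoids
    # (kx, ky, phase, weight) per component, in material coordinates
    vasc: tuple[tuple[float, float, float, float], ...]

    @property
    def apex_y(self) -> float:
        return self.lung_cy - max(self.semi_b)

    @property
    def base_y(self) -> float:
        return self.lung_cy + max(self.semi_b)

    @property
    def lung_height(self) -> float:
        return 2.0 * max(self.semi_b)


def _draw_anatomy(config: PhantomConfig) -> _Anatomy:
    """Sample seed-jittered lung geometry; the jitter varies shapes across
    seeds so segmentation on phantoms is a non-trivial learning problem."""
    s = float(config.image_size)
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 0xA11A])
    jit = lambda scale: float(rng.uniform(-scale, scale))  # noqa: E731
    cy = (0.46 + jit(0.02)) * s
    return _Anatomy(
        size=config.image_size,
        lung_cx=((0.33 + jit(0.02)) * s, (0.67 + jit(0.02)) * s),
        lung_cy=cy,
        semi_a=((0.135 + jit(0.012)) * s, (0.135 + jit(0.012)) * s),
        semi_b=((0.26 + jit(0.02)) * s, (0.26 + jit(0.02)) * s),
        exponent=float(rng.uniform(2.2, 2.8)),
        rib_period=float(rng.uniform(0.10, 0.14)) * s,
        rib_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
        vasc=tuple(
            (
                float(np.cos(theta) * 2.0 * np.pi / wavelength),
                float(np.sin(theta) * 2.0 * np.pi / wavelength),
                float(rng.uniform(0.0, 2.0 * np.pi)),
                float(rng.uniform(0.5, 1.0)),
            )
            for theta, wavelength in zip(
                rng.uniform(0.0, np.pi, 8), rng.uniform(0.06, 0.22, 8) * s
            )
        ),
    )


def _lung_support(anat: _Anatomy, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Boolean union of the two super-elliptical lungs at material coords."""
    inside = np.zeros(x.shape, dtype=bool)
    p = anat.exponent
    for cx, a, b in zip(anat.lung_cx, anat.semi_a, anat.semi_b):
        inside |= (
            np.abs((x - cx) / a) ** p + np.abs((y - anat.lung_cy) / b) ** p
        ) <= 1.0
    return inside


def _thorax_support(anat: _Anatomy, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    s = float(anat.size)
    return ((x - 0.5 * s) / (0.44 * s)) ** 2 + ((y - 0.52 * s) / (0.46 * s)) ** 2 <= 1.0


def _pattern(anat: _Anatomy, config: PhantomConfig, x: np.ndarray, y: np.ndarray):
    """Noise-free intensity and lung support at material coordinates."""
    lung = _lung_support(anat, x, y)
    thorax = _thorax_support(anat, x, y)
    img = np.full(x.shape, 0.10)
    img[thorax] = 0.35
    # rib-like bands plus a broadband vascular-like texture; both move with
    # the tissue.  The isotropic component matters: bands alone are
    # periodic in one direction, which would make in-plane motion partly
    # unobservable to an intensity-matching registrar (aperture problem).
    ribs = np.sin(2.0 * np.pi * y / anat.rib_period + anat.rib_phase)
    vasc = np.zeros_like(x)
    for kx, ky, phase, weight in anat.vasc:
        vasc += weight * np.sin(kx * x + ky * y + phase)
    vasc /= max(len(anat.vasc), 1)
    tex = config.texture_strength * (0.12 * ribs + 0.14 * vasc)
    img = np.where(lung, 0.70 + tex, img)
    return img, lung


# ---------------------------------------------------------------------------
# motion model


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _forward_displacement(
    anat: _Anatomy, config: PhantomConfig, phase: float, x: np.ndarray, y: np.ndarray
):
    """Forward motion f_phase(q): where the material point q moves to.

    Vertical component: amplitude * sin(pi * phase) * lung_height, weighted
    by a smooth apex-to-base ramp (0 at the apex, 1 at and below the base).
    Lateral component: a small expansion away from the midline with the
    same temporal envelope, largest near the base.
    """
    breath = float(config.breathing_amplitude) * np.sin(np.pi * float(phase))
    d = breath * anat.lung_height
    ramp = _smoothstep((y - anat.apex_y) / (anat.base_y - anat.apex_y))
    fy = d * ramp
    s = float(anat.size)
    fx = 0.25 * d * ((x - 0.5 * s) / (0.5 * s)) * ramp
    return fx, fy


def _invert_forward(anat, config, phase, px, py, n_iter: int = 12):
    """Material coords q with q + f(q) = p, by fixed-point iteration.

    The motion is a small, smooth perturbation of the identity (|grad f|
    well below 1 for amplitude <= 0.3), so the iteration converges fast.
    """
    qx, qy = px.copy(), py.copy()
    for _ in range(n_iter):
        fx, fy = _forward_displacement(anat, config, phase, qx, qy)
        qx = px - fx
        qy = py - fy
    return qx, qy


# ---------------------------------------------------------------------------
# public operations


def true_field(config: PhantomConfig, phase: float) -> DisplacementField:
    """Ground-truth backward field that warps the phase-``phase`` frame
    onto the phase-0 frame: the forward displacement on the pixel grid."""
    config.validate()
    anat = _draw_anatomy(config)
    s = config.image_size
    py, px = np.meshgrid(np.arange(s, dtype=np.float64), np.arange(s, dtype=np.float64), indexing="ij")
    fx, fy = _forward_displacement(anat, config, phase, px, py)
    return DisplacementField(fx.astype(np.float32), fy.astype(np.float32))


def generate_phantom(config: PhantomConfig, phase: float = 0.0):
    """Render one frame and its lung mask at a breathing phase in [0, 1].

    The mask is the exact support used to brighten the lung regions.
    Deterministic: the noise stream is derived from (seed, phase).
    """
    config.validate()
    if not 0.0 <= phase <= 1.0:
        raise ConfigurationError(f"phase must be in [0, 1], got {phase}")
    anat = _draw_anatomy(config)
    s = config.image_size
    py, px = np.meshgrid(np.arange(s, dtype=np.float64), np.arange(s, dtype=np.float64), indexing="ij")
    qx, qy = _invert_forward(anat, config, phase, px, py)
    img, lung = _pattern(anat, config, qx, qy)
    if config.noise_sd > 0:
        rng = np.random.default_rng(
            [int(config.seed) & 0x7FFFFFFF, int(round(phase * 1_000_000)) & 0x7FFFFFFF]
        )
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return img, lung.astype(np.uint8)


def generate_breathing_sequence(config: PhantomConfig) -> PhantomSequence:
    """One breathing cycle sampled at phases k/(n_frames-1).

    ``true_fields[k]`` warps frame k onto frame 0 (all-zero for k=0 and,
    by the sinusoidal envelope, for the final frame of a full cycle).
    """
    config.validate()
    n = config.n_frames
    phases = [0.0] if n == 1 else [k / (n - 1) for k in range(n)]
    frames, masks, fields = [], [], []
    for phase in phases:
        img, mask = generate_phantom(config, phase)
        frames.append(img)
        masks.append(mask)
        fields.append(true_field(config, phase))
    return PhantomSequence(frames, masks, fields, config)


def sample_affine(
    seed: int,
    rotation: tuple[float, float] = (-5.0, 5.0),
    scale: tuple[float, float] = (0.95, 1.05),
    translation: tuple[float, float] = (-0.05, 0.05),
    shear: tuple[float, float] = (-3.0, 3.0),
) -> AffineParams:
    """Draw affine augmentation parameters uniformly within the ranges.

    Rotation and shear are in degrees, translation is a fraction of the
    image side (drawn independently for x and y), scale is a factor.
    """
    for name, rng_ in (("rotation", rotation), ("scale", scale), ("translation", translation), ("shear", shear)):
        lo, hi = rng_
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ConfigurationError(f"invalid {name} range {rng_}")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    return AffineParams(
        rotation_deg=float(rng.uniform(*rotation)),
        scale=float(rng.uniform(*scale)),
        translation_frac=(float(rng.uniform(*translation)), float(rng.uniform(*translation))),
        shear_deg=float(rng.uniform(*shear)),
    )
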