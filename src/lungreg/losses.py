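"""Registration training losses and their weighted composite.

The composite objective for a source image I, target image J, source mask
S_I, target mask S_J and predicted field T is

    Loss = -lambda_ncc * NCC(I o T, J) + lambda_tv * TV(T)
           + lambda_bce * BCE(S_I o T, S_J)
           + lambda_l2 * L2(enc(S_I o T), enc(S_J))

with default weights (1.0, 5e-5, 1.0, 0.1) and an epsilon of 1e-5 guarding
the NCC denominator.  ``o`` is the differentiable backward warp.

Conventions fixed here:

* the NCC denominator is sqrt(Var(IoT) * Var(J) + eps) — one guard under
  the root covers both degenerate variances;
* TV is anisotropic exactly as specified: the x-plane is differenced along
  rows, the y-plane along columns, each term is the mean absolute forward
  difference, and the two means are averaged (a "full" mode differencing
  both planes along both axes is available);
* the latent L2 penalty is the mean of squared differences over all n*n
  code entries.

Every function accepts numpy arrays (returns a float) or autodiff tensors
(returns a Tensor that participates in backprop), and works on single
H x W rasters or (N, C, H, W) batches; batched statistics are computed
per image and averaged.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .errors import ConfigurationError
from .io_formats import DisplacementField


@dataclasses.dataclass
class LossWeights:
    """Composite-loss weights; defaults are the published settings."""

    lambda_ncc: float = 1.0
    lambda_tv: float = 5e-5
    lambda_bce: float = 1.0
    lambda_l2: float = 0.1
    eps: float = 1e-5

    def validate(self) -> "LossWeights":
        if min(self.lambda_ncc, self.lambda_tv, self.lambda_bce, self.lambda_l2) < 0:
            raise ConfigurationError("loss weights must be >= 0")
        if self.eps <= 0:
            raise ConfigurationError("eps must be > 0")
        return self


@dataclasses.dataclass
class LossBreakdown:
    """Per-term values (unweighted) and the weighted total.

    ``total`` is an autodiff Tensor when the field required gradients,
    otherwise a float; ``values()`` always returns plain floats.
    """

    ncc_term: object
    tv_term: object
    bce_term: object
    l2_term: object
    total: object

    def values(self) -> dict[str, float]:
        def f(v):
            return float(v.data) if isinstance(v, nn.Tensor) else float(v)

        return {
            "ncc": f(self.ncc_term),
            "tv": f(self.tv_term),
            "bce": f(self.bce_term),
            "l2": f(self.l2_term),
            "total": f(self.total),
        }


def _prep(x) -> tuple[nn.Tensor, bool]:
    """Promote to a (N, H, W, C) tensor; report whether input was a Tensor."""
    was_tensor = isinstance(x, nn.Tensor)
    t = nn.as_tensor(np.asarray(x, dtype=np.float32) if not was_tensor else x)
    if t.ndim == 2:
        t = t.reshape(1, *t.shape, 1)
    elif t.ndim != 4:
        raise ValueError(f"expected H x W or N x H x W x C, got shape {t.shape}")
    return t, was_tensor


def _finish(out: nn.Tensor, any_tensor: bool):
    return out if any_tensor else float(out.data)


def _check_shapes(a: nn.Tensor, b: nn.Tensor) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


# ---------------------------------------------------------------------------
# NCC


def ncc_loss(warped, target, eps: float = 1e-5):
    """Negative normalized cross-correlation, -cov / sqrt(VarI * VarJ + eps).

    Perfectly correlated non-constant inputs give about -1; a constant
    input yields 0 (zero covariance over the guarded denominator).
    """
    if eps <= 0:
        raise ConfigurationError(f"eps must be > 0, got {eps}")
    i, ti = _prep(warped)
    j, tj = _prep(target)
    _check_shapes(i, j)
    ax = (1, 2, 3)
    mi = i.mean(axis=ax, keepdims=True)
    mj = j.mean(axis=ax, keepdims=True)
    cov = ((i - mi) * (j - mj)).mean(axis=ax)
    var_i = (i - mi).square().mean(axis=ax)
    var_j = (j - mj).square().mean(axis=ax)
    out = (-(cov / (var_i * var_j + eps).sqrt())).mean()
    return _finish(out, ti or tj)


def _ncc_eq2(i: np.ndarray, j: np.ndarray, eps: float) -> float:
    """Direct moment form: cov and variances via E[(X - EX)...]."""
    di = i - i.mean()
    dj = j - j.mean()
    cov = (di * dj).mean()
    return float(-cov / np.sqrt((di**2).mean() * (dj**2).mean() + eps))


def _ncc_eq7(i: np.ndarray, j: np.ndarray, eps: float) -> float:
    """Expanded form: variances via E[X^2] - (E X)^2."""
    cov = ((i - i.mean()) * (j - j.mean())).mean()
    var_i = (i**2).mean() - i.mean() ** 2
    var_j = (j**2).mean() - j.mean() ** 2
    return float(-cov / np.sqrt(var_i * var_j + eps))


def ncc_equivalence_check(i: np.ndarray, j: np.ndarray, eps: float = 1e-5) -> float:
    """|direct - expanded| NCC loss: the two algebraic forms are identical
    up to floating-point rounding; returns the absolute difference."""
    i = np.asarray(i, dtype=np.float64)
    j = np.asarray(j, dtype=np.float64)
    if i.shape != j.shape:
        raise ValueError(f"shape mismatch: {i.shape} vs {j.shape}")
    return abs(_ncc_eq2(i, j, eps) - _ncc_eq7(i, j, eps))


# ---------------------------------------------------------------------------
# TV


def tv_loss(field, mode: str = "as_printed"):
    """Anisotropic total variation of a displacement field.

    ``as_printed``: mean |forward row-difference| of the x-plane plus mean
    |forward column-difference| of the y-plane, divided by 2.  ``full``:
    both planes differenced along both axes (sum of the four means, / 2).
    """
    if isinstance(field, DisplacementField):
        t = nn.as_tensor(np.stack([field.dx, field.dy], axis=-1)[None])
        was_tensor = False
    else:
        was_tensor = isinstance(field, nn.Tensor)
        t = nn.as_tensor(field)
        if t.ndim == 3:
            t = t.reshape(1, *t.shape)
    if t.ndim != 4 or t.shape[3] != 2:
        raise ValueError(f"expected a (N, H, W, 2) field, got shape {t.shape}")

    def d_row(p):
        return (p[:, 1:, :, :] - p[:, :-1, :, :]).abs().mean()

    def d_col(p):
        return (p[:, :, 1:, :] - p[:, :, :-1, :]).abs().mean()

    x_plane = t[..., 0:1]
    y_plane = t[..., 1:2]
    if mode == "as_printed":
        out = (d_row(x_plane) + d_col(y_plane)) * 0.5
    elif mode == "full":
        out = (d_row(x_plane) + d_col(x_plane) + d_row(y_plane) + d_col(y_plane)) * 0.5
    else:
        raise ValueError(f"unknown TV mode {mode!r}")
    return _finish(out, was_tensor)


# ---------------------------------------------------------------------------
# BCE and latent L2


def bce_loss(warped_mask, target_mask, clip: float = 1e-7):
    """Mean binary cross-entropy between a soft warped mask and the target.

    Predictions are clamped to [clip, 1 - clip] before the logs.
    """
    p, tp = _prep(warped_mask)
    s, ts = _prep(target_mask)
    _check_shapes(p, s)
    p = p.clip(clip, 1.0 - clip)
    out = -(s * p.log() + (1.0 - s) * (1.0 - p).log()).mean()
    return _finish(out, tp or ts)


def l2_latent_loss(code_warped, code_target):
    """Mean squared difference over all n x n latent-code entries."""
    a, ta = _prep(code_warped)
    b, tb = _prep(code_target)
    _check_shapes(a, b)
    out = (a - b).square().mean()
    return _finish(out, ta or tb)


# ---------------------------------------------------------------------------
# composite


def composite_loss(
    source,
    target,
    source_mask,
    target_mask,
    field,
    weights: LossWeights | None = None,
    encoder=None,
) -> LossBreakdown:
    """Warp the source image and mask by ``field`` and combine all terms.

    ``field`` may be a DisplacementField (evaluation; float total) or an
    (N, H, W, 2) Tensor from the deformation predictor (training; Tensor
    total carrying gradients to the field).  ``encoder`` must provide
    ``encode(batch) -> Tensor`` whenever ``lambda_l2 > 0``; the mask is
    warped *bilinearly* on this path so the overlap and latent penalties
    stay differentiable.
    """
    w = (weights or LossWeights()).validate()
    if w.lambda_l2 > 0 and encoder is None:
        raise ConfigurationError("an encoder is required when lambda_l2 > 0")

    src, _ = _prep(source)
    tgt, _ = _prep(target)
    smask, _ = _prep(source_mask)
    tmask, _ = _prep(target_mask)
    _check_shapes(src, tgt)
    _check_shapes(smask, tmask)

    if isinstance(field, DisplacementField):
        field_t = nn.as_tensor(np.stack([field.dx, field.dy], axis=-1)[None])
        differentiable = False
    else:
        field_t = nn.as_tensor(field)
        differentiable = isinstance(field, nn.Tensor)
    if field_t.ndim == 3:
        field_t = field_t.reshape(1, *field_t.shape)

    warped = nn.grid_sample(src.data, field_t)
    warped_mask = nn.grid_sample(smask.data, field_t)

    ncc = ncc_loss(warped, tgt, eps=w.eps)
    tv = tv_loss(field_t)
    bce = bce_loss(warped_mask, tmask)
    if w.lambda_l2 > 0:
        l2 = l2_latent_loss(encoder.encode(warped_mask), encoder.encode(tmask.data))
    else:
        l2 = nn.as_tensor(0.0)
    total = w.lambda_ncc * ncc + w.lambda_tv * tv + w.lambda_bce * bce + w.lambda_l2 * l2
    breakdown = LossBreakdown(ncc, tv, bce, l2, total)
    if not differentiable:
        return LossBreakdown(**{k: v for k, v in zip(
            ("ncc_term", "tv_term", "bce_term", "l2_term", "total"),
            [breakdown.values()[k] for k in ("ncc", "tv", "bce", "l2", "total")],
        )})
    return breakdown
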