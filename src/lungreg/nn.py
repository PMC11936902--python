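"""Compact reverse-mode autodiff core for the package's small CNNs.

Arrays are float32 in NHWC layout (batch, height, width, channels), which
keeps every convolution a plain BLAS matmul per kernel offset.  The op set
is exactly what the registration, segmentation and autoencoder models
need: 3x3/1x1 convolutions, 2x2 average pooling, nearest-neighbour 2x
upsampling, pointwise nonlinearities, reductions, slicing/concatenation,
and a bilinear ``grid_sample`` that is differentiable with respect to the
sampling field (the input raster is treated as data).  Backward passes are
hand-derived and are checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "concat",
    "conv2d",
    "avg_pool2",
    "upsample2",
    "grid_sample",
    "Module",
    "Conv2d",
    "Adam",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping --------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Reverse-mode sweep from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(_sum_to_shape(g, self.shape))
            other._accumulate(_sum_to_shape(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(_sum_to_shape(g * other.data, self.shape))
            other._accumulate(_sum_to_shape(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            self._accumulate(_sum_to_shape(g / other.data, self.shape))
            other._accumulate(_sum_to_shape(-g * out_data / other.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] += g
            self._accumulate(full)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    # -- pointwise ----------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def square(self):
        def bwd(g):
            self._accumulate(g * 2.0 * self.data)

        return Tensor(self.data * self.data, parents=(self,), backward=bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            self._accumulate(g * sign)

        return Tensor(np.abs(self.data), parents=(self,), backward=bwd)

    def clip(self, lo: float, hi: float):
        """Clamp; the gradient passes only where the input is strictly inside."""
        inside = ((self.data > lo) & (self.data < hi)).astype(np.float32)

        def bwd(g):
            self._accumulate(g * inside)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bwd)

    def relu(self):
        pos = (self.data > 0).astype(np.float32)

        def bwd(g):
            self._accumulate(g * pos)

        return Tensor(self.data * pos, parents=(self,), backward=bwd)

    def leaky_relu(self, slope: float = 0.1):
        fac = np.where(self.data > 0, np.float32(1.0), np.float32(slope))

        def bwd(g):
            self._accumulate(g * fac)

        return Tensor(self.data * fac, parents=(self,), backward=bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data.astype(np.float32), parents=(self,), backward=bwd)

    # -- reductions / shape -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).astype(np.float32))

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        def bwd(g):
            self._accumulate(g.reshape(self.shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(value) -> Tensor:
    if isinstance(value, Tensor):
        return value
    return Tensor(np.asarray(value, dtype=np.float32))


# ---------------------------------------------------------------------------
# structural ops (NHWC)


def concat(tensors: list[Tensor], axis: int = 3) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors), backward=bwd
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int = 1) -> Tensor:
    """Same-size 2-D convolution (stride 1) on NHWC input.

    ``weight`` has shape (kh, kw, C_in, C_out); the op is one matmul per
    kernel offset, which BLAS handles efficiently at these sizes.
    """
    x = as_tensor(x)
    n, h, w, c = x.shape
    kh, kw, c_in, o = weight.shape
    assert c == c_in, f"channel mismatch: input {c}, weight {c_in}"
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    out = np.zeros((n, h, w, o), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            out += xp[:, ki : ki + h, kj : kj + w, :] @ weight.data[ki, kj]
    if bias is not None:
        out += bias.data
    parents = (x, weight) + ((bias,) if bias is not None else ())

    def bwd(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(weight.data)
        gf = g.reshape(-1, o)
        for ki in range(kh):
            for kj in range(kw):
                patch = np.ascontiguousarray(xp[:, ki : ki + h, kj : kj + w, :])
                dw[ki, kj] = patch.reshape(-1, c) .T @ gf
                dxp[:, ki : ki + h, kj : kj + w, :] += g @ weight.data[ki, kj].T
        weight._accumulate(dw)
        if padding:
            x._accumulate(dxp[:, padding:-padding, padding:-padding, :])
        else:
            x._accumulate(dxp)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 1, 2)))

    return Tensor(out, parents=parents, backward=bwd)


def avg_pool2(x: Tensor) -> Tensor:
    n, h, w, c = x.shape
    assert h % 2 == 0 and w % 2 == 0, "avg_pool2 needs even spatial dims"
    out = x.data.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def bwd(g):
        gg = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) * 0.25
        x._accumulate(gg.astype(np.float32))

    return Tensor(out, parents=(x,), backward=bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def bwd(g):
        n, h2, w2, c = g.shape
        gg = g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))
        x._accumulate(gg.astype(np.float32))

    return Tensor(out, parents=(x,), backward=bwd)


def grid_sample(image: np.ndarray, field: Tensor) -> Tensor:
    """Backward-mapping bilinear warp, differentiable w.r.t. the field.

    ``image`` is an (N, H, W, C) array treated as constant data; ``field``
    is an (N, H, W, 2) tensor of (dx, dy) pixel displacements, dx along
    columns and dy along rows.  Output(p) samples image at p + field(p)
    with zeros padding, matching :func:`lungreg.warper.warp` with bilinear
    interpolation.
    """
    img = np.asarray(image, dtype=np.float32)
    n, h, w, c = img.shape
    assert field.shape == (n, h, w, 2), f"field shape {field.shape} != {(n, h, w, 2)}"
    rows, cols = np.meshgrid(
        np.arange(h, dtype=np.float32), np.arange(w, dtype=np.float32), indexing="ij"
    )
    px = cols[None] + field.data[..., 0]
    py = rows[None] + field.data[..., 1]
    x0 = np.floor(px)
    y0 = np.floor(py)
    wx = (px - x0)[..., None]
    wy = (py - y0)[..., None]
    n_idx = np.arange(n)[:, None, None]

    def gather(yy, xx):
        """Image values at integer coords, zero outside; (N, H, W, C)."""
        valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        yc = np.clip(yy, 0, h - 1).astype(np.intp)
        xc = np.clip(xx, 0, w - 1).astype(np.intp)
        return img[n_idx, yc, xc, :] * valid[..., None].astype(np.float32)

    i00 = gather(y0, x0)
    i01 = gather(y0, x0 + 1)
    i10 = gather(y0 + 1, x0)
    i11 = gather(y0 + 1, x0 + 1)
    out = (
        i00 * (1 - wx) * (1 - wy)
        + i01 * wx * (1 - wy)
        + i10 * (1 - wx) * wy
        + i11 * wx * wy
    )

    def bwd(g):
        dpx = (((i01 - i00) * (1 - wy) + (i11 - i10) * wy) * g).sum(axis=3)
        dpy = (((i10 - i00) * (1 - wx) + (i11 - i01) * wx) * g).sum(axis=3)
        field._accumulate(np.stack([dpx, dpy], axis=3).astype(np.float32))

    return Tensor(out.astype(np.float32), parents=(field,), backward=bwd)


# ---------------------------------------------------------------------------
# modules and optimisation


class Module:
    """Minimal parameter container with named state."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self) -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        self._collect("", self, out, set())
        return out

    @staticmethod
    def _collect(prefix, obj, out, seen):
        if id(obj) in seen:
            return
        seen.add(id(obj))
        if isinstance(obj, Parameter):
            out.append((prefix.rstrip("."), obj))
            return
        if isinstance(obj, Module):
            for name, val in sorted(vars(obj).items()):
                Module._collect(f"{prefix}{name}.", val, out, seen)
        elif isinstance(obj, (list, tuple)):
            for i, val in enumerate(obj):
                Module._collect(f"{prefix}{i}.", val, out, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict keys do not match model: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Conv2d(Module):
    """Stride-1 convolution layer with He-style initialisation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 zero_init: bool = False):
        self.padding = kernel // 2
        if zero_init:
            w = np.zeros((kernel, kernel, in_ch, out_ch), np.float32)
        else:
            std = np.sqrt(2.0 / (in_ch * kernel * kernel))
            w = rng.normal(0.0, std, (kernel, kernel, in_ch, out_ch)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class Adam:
    """Adam optimiser with bias-corrected moments and optional global
    gradient-norm clipping (a stabiliser for the registration objective,
    whose warp gradients are locally rough)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        if self.clip_norm is not None:
            sq = sum(float((p.grad ** 2).sum()) for p in self.params if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                fac = np.float32(self.clip_norm / norm)
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= fac
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
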