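"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine purpose-built for 3D segmentation networks: the op
set covers pointwise (1x1x1) channel-mixing convolutions, depthwise 3D
convolutions of arbitrary odd kernel edge (FFT-based, so very large kernels
cost the same as small ones), GELU, channel softmax / cross-entropy,
nearest-neighbour upsampling, channel concatenation, and the elementwise and
reduction primitives needed to compose normalisation layers and Dice-style
losses. Everything runs in float32 by default; float64 is supported for
verification against finite differences.

Array layout convention is channels-second: ``(N, C, D, H, W)``.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy import fft as sfft
from scipy.special import erf

# ---------------------------------------------------------------------------
# Tensor and graph machinery

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager that disables graph construction (pure inference)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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
                node._backward()
        # Break closure reference cycles so the graph frees by refcount.
        for node in topo:
            node._backward = None
            node._parents = ()
            if not node.requires_grad:
                node.grad = None

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, power(_as_tensor(other), -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}, name={self.name!r})"


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    # Keep python scalars at float32 so constants never promote a float32
    # graph to float64 (float64 graphs are unaffected: f64 op f32 -> f64).
    if isinstance(x, (int, float)):
        return Tensor(np.asarray(x, dtype=np.float32))
    return Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if not _GRAD_ENABLED[0]:
        return out
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward(out)
    return out


# ---------------------------------------------------------------------------
# Elementwise and reduction primitives


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bwd(out):
        def run():
            a.accumulate(_unbroadcast(out.grad, a.shape))
            b.accumulate(_unbroadcast(out.grad, b.shape))

        return run

    return _make(data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bwd(out):
        def run():
            a.accumulate(_unbroadcast(out.grad * b.data, a.shape))
            b.accumulate(_unbroadcast(out.grad * a.data, b.shape))

        return run

    return _make(data, (a, b), bwd)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data**exponent

    def bwd(out):
        def run():
            a.accumulate(out.grad * exponent * a.data ** (exponent - 1.0))

        return run

    return _make(data, (a,), bwd)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(out):
        def run():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a.accumulate(np.broadcast_to(g, a.shape).copy())

        return run

    return _make(data, (a,), bwd)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def gelu(a) -> Tensor:
    """Gaussian-error linear unit, exact form x * Phi(x)."""
    a = _as_tensor(a)
    x = a.data
    phi_cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
    data = x * phi_cdf

    def bwd(out):
        def run():
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            a.accumulate(out.grad * (phi_cdf + x * pdf))

        return run

    return _make(data, (a,), bwd)


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.shape[1] for t in tensors]

    def bwd(out):
        def run():
            start = 0
            for t, c in zip(tensors, sizes):
                t.accumulate(out.grad[:, start : start + c])
                start += c

        return run

    return _make(data, tensors, bwd)


# ---------------------------------------------------------------------------
# Convolutions


def conv1x1(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Pointwise channel-mixing convolution: w is (C_out, C_in)."""
    x, w = _as_tensor(x), _as_tensor(w)
    data = np.einsum("oc,nc...->no...", w.data, x.data, optimize=True)
    if b is not None:
        data = data + b.data.reshape((1, -1) + (1,) * (data.ndim - 2))
    parents = (x, w) if b is None else (x, w, b)

    def bwd(out):
        def run():
            g = out.grad
            x.accumulate(np.einsum("oc,no...->nc...", w.data, g, optimize=True))
            w.accumulate(np.einsum("no...,nc...->oc", g, x.data, optimize=True))
            if b is not None:
                b.accumulate(g.sum(axis=(0,) + tuple(range(2, g.ndim))))

        return run

    return _make(data, parents, bwd)


_FFT_AXES = (-3, -2, -1)


def _roll_slice(z: np.ndarray, shifts, sizes) -> np.ndarray:
    """Roll the trailing 3 axes by ``shifts`` and keep the first ``sizes``
    entries of each (circular index extraction)."""
    z = np.roll(z, shifts, axis=_FFT_AXES)
    return np.ascontiguousarray(z[..., : sizes[0], : sizes[1], : sizes[2]])


def _corr_same(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """'Same'-size cross-correlation with zero padding (reference path for
    callers that do not need gradients)."""
    sp, ke = x.shape[-3:], k.shape[-3:]
    fshape = [sfft.next_fast_len(s + e - 1, real=True) for s, e in zip(sp, ke)]
    Xf = sfft.rfftn(x, fshape, axes=_FFT_AXES)
    Kf = sfft.rfftn(k, fshape, axes=_FFT_AXES)
    y = sfft.irfftn(Xf * np.conj(Kf), fshape, axes=_FFT_AXES)
    return _roll_slice(y, [e // 2 for e in ke], sp)


def depthwise_conv3d(
    x: Tensor, k: Tensor, b: Tensor | None = None, stride: int = 1
) -> Tensor:
    """Depthwise 3D cross-correlation with 'same' zero padding.

    ``x`` is (N, C, D, H, W); ``k`` is (C, e, e, e) with odd edge e; the
    optional bias ``b`` is (C,). ``stride`` subsamples the output (used for
    stride-2 downsampling). Implemented with real FFTs at size N + e - 1
    (which also keeps circular correlation alias-free for every lag the
    kernel needs), so the cost is nearly independent of kernel edge. The
    input and kernel spectra are cached for the backward pass: the input
    gradient is one circular convolution and the kernel gradient one circular
    correlation on the same grid.
    """
    x, k = _as_tensor(x), _as_tensor(k)
    edge = k.shape[-3:]
    if any(e % 2 == 0 for e in edge):
        raise ValueError(f"kernel edges must be odd, got {edge}")
    sp = x.shape[-3:]
    centers = [e // 2 for e in edge]
    fshape = [sfft.next_fast_len(s + e - 1, real=True) for s, e in zip(sp, edge)]
    Xf = sfft.rfftn(x.data, fshape, axes=_FFT_AXES)
    Kf = sfft.rfftn(k.data, fshape, axes=_FFT_AXES)
    # y[i] = sum_t x[i + t - c] k[t]  (circular corr, alias-free by padding)
    y = _roll_slice(
        sfft.irfftn(Xf * np.conj(Kf), fshape, axes=_FFT_AXES), centers, sp
    )
    if stride != 1:
        y = np.ascontiguousarray(y[..., ::stride, ::stride, ::stride])
    y = y.astype(x.dtype, copy=False)
    if b is not None:
        y = y + b.data.reshape((1, -1, 1, 1, 1))
    parents = (x, k) if b is None else (x, k, b)

    def bwd(out):
        def run():
            g = out.grad
            if stride != 1:
                gfull = np.zeros(x.shape, dtype=g.dtype)
                gfull[..., ::stride, ::stride, ::stride] = g
                g = gfull
            Gf = sfft.rfftn(g, fshape, axes=_FFT_AXES)
            # dL/dx[j] = sum_i g[i] k[j + c - i]: circular convolution g * k
            gx_full = sfft.irfftn(Gf * Kf, fshape, axes=_FFT_AXES)
            gx = np.roll(gx_full, [-c for c in centers], axis=_FFT_AXES)[
                ..., : sp[0], : sp[1], : sp[2]
            ]
            x.accumulate(np.ascontiguousarray(gx).astype(x.dtype, copy=False))
            # dL/dk[t] = sum_{n,i} x[i + t - c] g[i]: circular corr, batch-summed
            prod = (Xf * np.conj(Gf)).sum(axis=0)
            gk_full = sfft.irfftn(prod, fshape, axes=_FFT_AXES)
            gk = _roll_slice(gk_full, centers, edge)
            k.accumulate(gk.astype(k.dtype, copy=False))
            if b is not None:
                b.accumulate(out.grad.sum(axis=(0, 2, 3, 4)))

        return run

    return _make(y, parents, bwd)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Double each spatial dimension by voxel repetition (exact adjoint: block sum)."""
    x = _as_tensor(x)
    data = (
        x.data.repeat(2, axis=-3).repeat(2, axis=-2).repeat(2, axis=-1)
    )

    def bwd(out):
        def run():
            g = out.grad
            n, c, d, h, w = g.shape
            g = g.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))
            x.accumulate(g)

        return run

    return _make(data, (x,), bwd)


# ---------------------------------------------------------------------------
# Softmax / losses


def softmax_channels(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)

    def bwd(out):
        def run():
            g = out.grad
            dot = (g * s).sum(axis=1, keepdims=True)
            x.accumulate(s * (g - dot))

        return run

    return _make(s, (x,), bwd)


def cross_entropy_fg(logits: Tensor, fg_mask: np.ndarray) -> Tensor:
    """Mean voxelwise cross-entropy of 2-channel logits against a binary
    foreground mask (channel 0 = background, channel 1 = foreground)."""
    logits = _as_tensor(logits)
    z = logits.data
    m = z.max(axis=1, keepdims=True)
    lse = m + np.log(np.exp(z - m).sum(axis=1, keepdims=True))
    fg = np.asarray(fg_mask).astype(z.dtype)
    target_logit = np.where(fg.astype(bool), z[:, 1], z[:, 0])
    n_vox = target_logit.size
    loss = float((lse[:, 0] - target_logit).sum() / n_vox)

    def bwd(out):
        def run():
            p = np.exp(z - lse)  # softmax
            onehot = np.stack([1.0 - fg, fg], axis=1)
            logits.accumulate(out.grad * (p - onehot) / n_vox)

        return run

    return _make(np.asarray(loss, dtype=z.dtype), (logits,), bwd)


def soft_dice_loss(prob_fg: Tensor, fg_mask: np.ndarray, eps: float = 1e-5) -> Tensor:
    """1 - soft Dice between a foreground probability map and a binary mask."""
    prob_fg = _as_tensor(prob_fg)
    g = np.asarray(fg_mask).astype(prob_fg.dtype)
    inter = tsum(mul(prob_fg, g))
    denom = add(tsum(prob_fg), float(g.sum()))
    dice = mul(add(mul(inter, 2.0), eps), power(add(denom, eps), -1.0))
    return add(1.0, mul(dice, -1.0))


# ---------------------------------------------------------------------------
# Parameters and optimiser


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data, name: str = ""):
        super().__init__(np.asarray(data), requires_grad=True, name=name)


class Adam:
    """Adam optimiser with the standard bias-corrected moments."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
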