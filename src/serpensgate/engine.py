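"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains and runs its detector on CPU, so the tensor engine is
deliberately small: a :class:`Tensor` wrapping a float32 ``numpy`` array, a
closure-based tape, and exactly the operators the network needs (dense and
batched matmul, 2-D convolution via im2col, stride-1 max pooling, nearest
upsampling, normalisation statistics, bilinear map sampling, elementwise
nonlinearities and reductions). Gradients are accumulated into ``.grad`` by a
topological backward pass.

Shapes follow the NCHW convention used throughout the detector.
"""

from __future__ import annotations

import contextlib
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference / metrics)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ---- bookkeeping -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return self.data.item()

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._prev:
                # free the tape as we go; leaf grads survive
                node._backward = None
                node._prev = ()

    # ---- elementwise arithmetic -----------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._prev:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._prev:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._prev:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out._prev:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = _make(y, (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = _make(y, (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g * 0.5 / y)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _make(y, (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(y, (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(self.data * s, (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g * s * (1.0 + self.data * (1.0 - s)))
        return out

    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def clamp(self, lo: float | None = None, hi: float | None = None):
        """Clamp values; gradient is passed through inside the interval only."""
        y = np.clip(self.data, lo, hi)
        out = _make(y, (self,))
        if out._prev:
            inside = np.ones_like(self.data, dtype=bool)
            if lo is not None:
                inside &= self.data > lo
            if hi is not None:
                inside &= self.data < hi
            out._backward = lambda g: self._accum(g * inside)
        return out

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _make(self.data.transpose(axes), (self,))
        if out._prev:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._prev:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._prev:
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        idx = self.data.argmax(axis=axis)
        y = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            y = y.squeeze(axis)
        out = _make(y, (self,))
        if out._prev:
            def bw(g):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
                self._accum(full)
            out._backward = bw
        return out

    # ---- linear algebra --------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._prev:
            def bw(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accum(_unbroadcast(gb, other.shape))
            out._backward = bw
        return out

    __matmul__ = matmul


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, children: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        prev = tuple(c for c in children if c.requires_grad or c._prev)
        if any(c.requires_grad for c in children):
            out.requires_grad = True
            out._prev = prev
    return out


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._prev:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.stack([t.data for t in tensors], axis=axis), tensors)
    if out._prev:
        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from primitive ops (max is detached)."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Fast path: 1x1 stride-1 convolution as a channel matmul."""
    B, C, H, W = x.shape
    Cout = w.shape[0]
    wmat = w.data.reshape(Cout, C)
    xf = x.data.reshape(B, C, H * W)
    y = np.matmul(wmat, xf)
    if b is not None:
        y += b.data[:, None]
    children = (x, w) if b is None else (x, w, b)
    out = _make(y.reshape(B, Cout, H, W), children)
    if out._prev:
        def bw(g):
            gf = g.reshape(B, Cout, H * W)
            if b is not None and b.requires_grad:
                b._accum(gf.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.matmul(gf, xf.transpose(0, 2, 1)).sum(axis=0)
                w._accum(gw.reshape(w.shape))
            if x.requires_grad:
                gx = np.matmul(wmat.T, gf)
                x._accum(gx.reshape(B, C, H, W))
        out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NCHW input, OIHW weight, via im2col + BLAS matmul."""
    B, C, H, W = x.shape
    Cout, Cin, kh, kw = w.shape
    assert Cin == C, f"channel mismatch: input {C}, weight {Cin}"
    if kh == kw == 1 and stride == 1 and padding == 0:
        return _conv1x1(x, w, b)
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # (B, C, kh, kw, Ho, Wo) -> (B, C*kh*kw, Ho*Wo): one copy, output needs none
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)
                                ).reshape(B, C * kh * kw, Ho * Wo)
    wmat = w.data.reshape(Cout, C * kh * kw)
    y = np.matmul(wmat, cols)
    if b is not None:
        y += b.data[:, None]
    children = (x, w) if b is None else (x, w, b)
    out = _make(y.reshape(B, Cout, Ho, Wo), children)
    if out._prev:
        def bw(g):
            gf = g.reshape(B, Cout, Ho * Wo)
            if b is not None and b.requires_grad:
                b._accum(gf.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
                w._accum(gw.reshape(w.shape))
            if x.requires_grad:
                gcols = np.matmul(wmat.T, gf).reshape(B, C, kh, kw, Ho, Wo)
                gx = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += gcols[:, :, i, j]
                if p:
                    gx = gx[:, :, p:-p, p:-p]
                x._accum(gx)
        out._backward = bw
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float,
                mean: np.ndarray | None = None, var: np.ndarray | None = None
                ) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused per-channel batch normalisation.

    With `mean`/`var` omitted, batch statistics over (B, H, W) are computed and
    differentiated through (training mode); when supplied they are treated as
    constants (inference mode). Returns (output, mean, var) so callers can
    update running statistics.
    """
    B, C, H, W = x.shape
    n = B * H * W
    train_stats = mean is None
    if train_stats:
        mean = x.data.mean(axis=(0, 2, 3))
        var = ((x.data - mean[:, None, None]) ** 2).mean(axis=(0, 2, 3))
    inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mean[:, None, None].astype(np.float32)) * inv_std[:, None, None]
    y = xhat * gamma.data[:, None, None] + beta.data[:, None, None]
    out = _make(y, (x, gamma, beta))
    if out._prev:
        def bw(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxh = g * gamma.data[:, None, None]
                if train_stats:
                    sum_gxh = gxh.sum(axis=(0, 2, 3))
                    sum_gxh_xhat = (gxh * xhat).sum(axis=(0, 2, 3))
                    gx = (gxh - (sum_gxh[:, None, None]
                                 + xhat * sum_gxh_xhat[:, None, None]) / n) \
                        * inv_std[:, None, None]
                else:
                    gx = gxh * inv_std[:, None, None]
                x._accum(gx.astype(np.float32))
        out._backward = bw
    return out, np.asarray(mean), np.asarray(var)


def maxpool2d(x: Tensor, k: int, stride: int = 1, padding: int | None = None) -> Tensor:
    """Max pooling; default padding k//2 keeps stride-1 pooling shape-preserving."""
    B, C, H, W = x.shape
    p = k // 2 if padding is None else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf) if p else x.data
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(B, C, Ho, Wo, k * k)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = _make(y, (x,))
    if out._prev:
        def bw(g):
            gx = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=np.float32)
            ki, kj = np.unravel_index(idx, (k, k))
            bi, ci, hi, wi = np.indices((B, C, Ho, Wo), sparse=False)
            np.add.at(gx, (bi, ci, hi * stride + ki, wi * stride + kj), g)
            if p:
                gx = gx[:, :, p:-p, p:-p]
            x._accum(gx)
        out._backward = bw
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    B, C, H, W = x.shape
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = _make(y, (x,))
    if out._prev:
        out._backward = lambda g: x._accum(
            g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))
    return out


def bilinear_sample(features: Tensor, ys: Tensor, xs: Tensor) -> Tensor:
    """Sample `features` (B,C,H,W) at fractional coordinates.

    `ys`, `xs` have shape (B, K, H', W') in feature-pixel units; the result has
    shape (B, C, K, H', W'). Coordinates are clamped to the valid extent; the
    coordinate gradient is the exact bilinear-weight derivative (zero where the
    clamp is active). Integer coordinates reproduce input values exactly.
    """
    B, C, H, W = features.shape
    yc = np.clip(ys.data, 0.0, H - 1.0)
    xc = np.clip(xs.data, 0.0, W - 1.0)
    y0 = np.floor(yc).astype(np.int64)
    x0 = np.floor(xc).astype(np.int64)
    y0 = np.minimum(y0, H - 2) if H > 1 else np.zeros_like(y0)
    x0 = np.minimum(x0, W - 2) if W > 1 else np.zeros_like(x0)
    y1, x1 = y0 + (1 if H > 1 else 0), x0 + (1 if W > 1 else 0)
    fy = (yc - y0).astype(np.float32)
    fx = (xc - x0).astype(np.float32)
    bidx = np.arange(B)[:, None, None, None]
    f = features.data
    # gather the 4 corners: shape (B, C, K, H', W')
    def corner(yi, xi):
        return f[bidx, :, yi, xi].transpose(0, 4, 1, 2, 3)
    v00, v01 = corner(y0, x0), corner(y0, x1)
    v10, v11 = corner(y1, x0), corner(y1, x1)
    wy, wx = fy[:, None], fx[:, None]
    out_data = (v00 * (1 - wy) * (1 - wx) + v01 * (1 - wy) * wx
                + v10 * wy * (1 - wx) + v11 * wy * wx)
    out = _make(out_data, (features, ys, xs))
    if out._prev:
        def bw(g):
            if features.requires_grad:
                gf = np.zeros_like(f)
                gT = g.transpose(0, 2, 3, 4, 1)  # (B,K,H',W',C)
                wyb, wxb = fy[..., None], fx[..., None]
                np.add.at(gf.transpose(0, 2, 3, 1), (bidx, y0, x0), gT * (1 - wyb) * (1 - wxb))
                np.add.at(gf.transpose(0, 2, 3, 1), (bidx, y0, x1), gT * (1 - wyb) * wxb)
                np.add.at(gf.transpose(0, 2, 3, 1), (bidx, y1, x0), gT * wyb * (1 - wxb))
                np.add.at(gf.transpose(0, 2, 3, 1), (bidx, y1, x1), gT * wyb * wxb)
                features._accum(gf)
            if ys.requires_grad or xs.requires_grad:
                dy = ((v10 - v00) * (1 - wx) + (v11 - v01) * wx)
                dx = ((v01 - v00) * (1 - wy) + (v11 - v10) * wy)
                in_y = ((ys.data > 0) & (ys.data < H - 1)).astype(np.float32)
                in_x = ((xs.data > 0) & (xs.data < W - 1)).astype(np.float32)
                if ys.requires_grad:
                    ys._accum((g * dy).sum(axis=1) * in_y)
                if xs.requires_grad:
                    xs._accum((g * dx).sum(axis=1) * in_x)
        out._backward = bw
    return out
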