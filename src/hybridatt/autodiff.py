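"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains its networks on CPU with plain numpy; this module
provides the small set of differentiable operations the model needs
(dense algebra, 1-D/2-D convolution, pooling, the usual nonlinearities,
a numerically stable softmax). Gradients are accumulated by walking the
tape in reverse topological order. All buffers are float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "conv1d",
    "conv2d",
    "maxpool1d",
    "avgpool1d",
    "avgpool2d",
    "softmax",
    "sigmoid",
    "tanh",
    "relu",
    "clip",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))
        a, b = self, other

        def bwd(g):
            if a.ndim == 2 and b.ndim == 1:
                if a.requires_grad:
                    a._accum(np.outer(g, b.data))
                if b.requires_grad:
                    b._accum(a.data.T @ g)
            elif a.ndim == 1 and b.ndim == 2:
                if a.requires_grad:
                    a._accum(b.data @ g)
                if b.requires_grad:
                    b._accum(np.outer(a.data, g))
            elif a.ndim == 1 and b.ndim == 1:
                if a.requires_grad:
                    a._accum(g * b.data)
                if b.requires_grad:
                    b._accum(g * a.data)
            else:  # 2D @ 2D
                if a.requires_grad:
                    a._accum(g @ b.data.T)
                if b.requires_grad:
                    b._accum(a.data.T @ g)

        out._backward = bwd
        return out

    # -- shape -------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bwd
        return out

    # -- reductions --------------------------------------------------

    def sum(self, axis=None):
        out = Tensor(self.data.sum(axis=axis), self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                self._accum(np.broadcast_to(np.expand_dims(g, axis),
                                            self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / n

    def dot(self, other):
        return self @ other


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities --------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * y * (1.0 - y))

    out._backward = bwd
    return out


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = np.tanh(x.data)
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * (1.0 - y * y))

    out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0.0))

    out._backward = bwd
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g / x.data)

    out._backward = bwd
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where the input is inside [lo, hi]."""
    x = as_tensor(x)
    out = Tensor(np.clip(x.data, lo, hi), x.requires_grad, (x,))
    inside = (x.data >= lo) & (x.data <= hi)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * inside)

    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-subtracted exponentials)."""
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

    out._backward = bwd
    return out


# -- joins -----------------------------------------------------------


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bwd
    return out


# -- convolution and pooling ----------------------------------------


def conv_out_len(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """1-D cross-correlation: x (Cin, L), w (Cout, Cin, K), b (Cout,)."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    cin, n = x.data.shape
    cout, _, k = w.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad)))
    n_out = conv_out_len(n, k, stride, pad)
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)[:, ::stride]
    cols = cols[:, :n_out]  # (Cin, Lout, K)
    y = np.einsum("oik,ilk->ol", w.data, cols, optimize=True) + b.data[:, None]
    out = Tensor(y, x.requires_grad or w.requires_grad or b.requires_grad,
                 (x, w, b))

    def bwd(g):
        if b.requires_grad:
            b._accum(g.sum(axis=1))
        if w.requires_grad:
            w._accum(np.einsum("ol,ilk->oik", g, cols, optimize=True))
        if x.requires_grad:
            dcols = np.einsum("ol,oik->ilk", g, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            idx = stride * np.arange(n_out)
            for kk in range(k):
                np.add.at(dxp, (slice(None), idx + kk), dcols[:, :, kk])
            x._accum(dxp[:, pad:pad + n] if pad else dxp)

    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride=(1, 1), pad=(0, 0)) -> Tensor:
    """2-D cross-correlation: x (Cin, H, W), w (Cout, Cin, KH, KW), b (Cout,)."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    cin, h, wd = x.data.shape
    cout, _, kh, kw = w.data.shape
    sh, sw = stride
    ph, pw = pad
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    h_out = conv_out_len(h, kh, sh, ph)
    w_out = conv_out_len(wd, kw, sw, pw)
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = cols[:, ::sh, ::sw][:, :h_out, :w_out]  # (Cin, Ho, Wo, KH, KW)
    y = np.einsum("oikl,ihwkl->ohw", w.data, cols, optimize=True)
    y = y + b.data[:, None, None]
    out = Tensor(y, x.requires_grad or w.requires_grad or b.requires_grad,
                 (x, w, b))

    def bwd(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(1, 2)))
        if w.requires_grad:
            w._accum(np.einsum("ohw,ihwkl->oikl", g, cols, optimize=True))
        if x.requires_grad:
            dcols = np.einsum("ohw,oikl->ihwkl", g, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            hi = sh * np.arange(h_out)
            wi = sw * np.arange(w_out)
            for a in range(kh):
                for bb in range(kw):
                    np.add.at(dxp, (slice(None), hi[:, None] + a, wi[None, :] + bb),
                              dcols[:, :, :, a, bb])
            x._accum(dxp[:, ph:ph + h, pw:pw + wd] if (ph or pw) else dxp)

    out._backward = bwd
    return out


def maxpool1d(x: Tensor, size: int, stride: int, pad: int = 0) -> Tensor:
    """Max pooling over the last axis of x (C, L); padding with -inf."""
    x = as_tensor(x)
    c, n = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad)), constant_values=-np.inf)
    n_out = conv_out_len(n, size, stride, pad)
    wins = np.lib.stride_tricks.sliding_window_view(xp, size, axis=1)[:, ::stride]
    wins = wins[:, :n_out]
    arg = wins.argmax(axis=2)
    y = np.take_along_axis(wins, arg[:, :, None], axis=2)[:, :, 0]
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        rows = np.repeat(np.arange(c), n_out)
        cols_ = (stride * np.tile(np.arange(n_out), c) + arg.ravel())
        np.add.at(dxp, (rows, cols_), g.ravel())
        x._accum(dxp[:, pad:pad + n] if pad else dxp)

    out._backward = bwd
    return out


def avgpool1d(x: Tensor, size: int, stride: int, pad: int = 0) -> Tensor:
    """Average pooling (count includes zero padding, torch-style default)."""
    x = as_tensor(x)
    c, n = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad)))
    n_out = conv_out_len(n, size, stride, pad)
    wins = np.lib.stride_tricks.sliding_window_view(xp, size, axis=1)[:, ::stride]
    y = wins[:, :n_out].mean(axis=2)
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        idx = stride * np.arange(n_out)
        gs = g / size
        for kk in range(size):
            np.add.at(dxp, (slice(None), idx + kk), gs)
        x._accum(dxp[:, pad:pad + n] if pad else dxp)

    out._backward = bwd
    return out


def avgpool2d(x: Tensor, size=(1, 1), stride=(1, 1), pad=(0, 0)) -> Tensor:
    """2-D average pooling over (C, H, W); count includes zero padding."""
    x = as_tensor(x)
    c, h, wd = x.data.shape
    kh, kw = size
    sh, sw = stride
    ph, pw = pad
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    h_out = conv_out_len(h, kh, sh, ph)
    w_out = conv_out_len(wd, kw, sw, pw)
    wins = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    wins = wins[:, ::sh, ::sw][:, :h_out, :w_out]
    y = wins.mean(axis=(3, 4))
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        hi = sh * np.arange(h_out)
        wi = sw * np.arange(w_out)
        gs = g / (kh * kw)
        for a in range(kh):
            for bb in range(kw):
                np.add.at(dxp, (slice(None), hi[:, None] + a, wi[None, :] + bb), gs)
        x._accum(dxp[:, ph:ph + h, pw:pw + wd] if (ph or pw) else dxp)

    out._backward = bwd
    return out
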