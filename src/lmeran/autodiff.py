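"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the model needs: broadcasting arithmetic,
(batched) matrix multiplication, softmax, sigmoid, log/exp, relu, reductions,
reshaping/slicing, concatenation, clipping and 2-D convolution.  Gradients are
accumulated by reverse topological traversal from the tensor ``backward`` is
called on.  All tensors hold ``float64`` data unless constructed otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype != np.float32:   # float32 preserved, all else promoted
            data = data.astype(np.float64, copy=False)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        if isinstance(other, (int, float)):   # dtype-preserving scalar path
            out = self._make(self.data + other, (self,), None)
            out._backward = lambda g: self._accum(g)
            return out
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = self._make(self.data * other, (self,), None)
            out._backward = lambda g: self._accum(g * other)
            return out
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __pow__(self, exponent: float):
        out = self._make(self.data**exponent, (self,), None)
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(np.matmul(self.data, other.data), (self, other), None)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, other.data.swapaxes(-1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(self.data.swapaxes(-1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        y = np.exp(self.data)
        out = self._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def relu(self):
        out = self._make(np.maximum(self.data, 0.0), (self,), None)
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(y, (self,), None)
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = self._make(y, (self,), None)

        def bw(g):
            inner = (g * y).sum(axis=axis, keepdims=True)
            self._accum((g - inner) * y)

        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only through unclipped entries."""
        out = self._make(np.clip(self.data, lo, hi), (self,), None)
        mask = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = self._make(self.data.reshape(shape), (self,), None)
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out._parents = tuple(tensors)

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    draw_dtype = np.float32 if x.data.dtype == np.float32 else np.float64
    mask = (rng.random(x.data.shape, dtype=draw_dtype) >= rate).astype(x.data.dtype)
    mask /= draw_dtype(1.0 - rate)
    return x * Tensor(mask)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols, x_shape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                cols[:, :, :, :, i, j]
            )
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, via im2col."""
    n = x.data.shape[0]
    cout, cin, kh, kw = weight.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    flat = cols @ weight.data.reshape(cout, -1).T
    if bias is not None:
        flat = flat + bias.data
    y = flat.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    parents = [x, weight] + ([bias] if bias is not None else [])
    out = Tensor(y)
    out.requires_grad = any(p.requires_grad for p in parents)
    if not out.requires_grad:
        return out
    out._parents = tuple(parents)

    def bw(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        if bias is not None and bias.requires_grad:
            bias._accum(gflat.sum(axis=0))
        if weight.requires_grad:
            gw = gflat.T @ cols
            weight._accum(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = gflat @ weight.data.reshape(cout, -1)
            x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, padding, ho, wo))

    out._backward = bw
    return out
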