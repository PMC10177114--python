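"""Minimal reverse-mode autodiff over numpy arrays.

This is a deliberately small engine: a :class:`Tensor` wraps a float32
ndarray, records the operations applied to it, and :meth:`Tensor.backward`
walks the graph in reverse topological order accumulating gradients.  Only
the operations the detector needs exist — elementwise arithmetic, matmul,
reductions, indexing/reshaping/concatenation, relu/sigmoid/softmax, a
piecewise Huber, strided 2-D convolution with SAME(ceil) padding, and
nearest-neighbour 2x up-sampling.  Everything is validated against
finite-difference gradients in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample2x"]

_F32 = np.float32


def _as_array(value) -> np.ndarray:
    return np.asarray(value, dtype=_F32)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # adopt freshly allocated float32 temporaries, copy views/casts
            if grad.dtype == _F32 and grad.base is None and grad.flags.owndata and grad.flags.writeable:
                self.grad = grad
            else:
                self.grad = grad.astype(_F32)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- elementwise arithmetic --------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        """Elementwise power with a constant exponent.

        The derivative at base exactly 0 is defined as 0 (correct limit for
        exponent > 1, and the convention we need for focal terms at pt = 1).
        """
        out_data = np.power(self.data, _F32(exponent))

        def backward():
            if self.requires_grad:
                base = self.data
                with np.errstate(divide="ignore", invalid="ignore"):
                    d = exponent * np.power(base, _F32(exponent - 1.0))
                d = np.where(np.isfinite(d), d, 0.0)
                self._accum(out.grad * d)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def clip_min(self, floor: float) -> "Tensor":
        """Lower clamp; gradient flows only where the input is above the floor."""
        out_data = np.maximum(self.data, _F32(floor))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > floor))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0.0))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x))).astype(_F32)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data * (1.0 - out_data))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward():
            if self.requires_grad:
                g = out.grad
                dot = (g * p).sum(axis=axis, keepdims=True)
                self._accum(p * (g - dot))

        out = Tensor._make(p, (self,), backward)
        return out

    def huber(self, delta: float = 1.0) -> "Tensor":
        """Elementwise Huber penalty: 0.5 a^2 for |a| <= delta, else delta|a| - 0.5 delta^2."""
        a = self.data
        absa = np.abs(a)
        out_data = np.where(absa <= delta, 0.5 * a * a, delta * absa - 0.5 * delta * delta).astype(_F32)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * np.clip(a, -delta, delta))

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- reductions, shaping, indexing -------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def transpose(self, axes: tuple[int, ...]) -> "Tensor":
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, key, out.grad)
                self._accum(g)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ out.grad, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(start, stop)
                t._accum(out.grad[tuple(sl)])

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


def _same_ceil_pad(dim: int, stride: int, k: int) -> tuple[int, int, int]:
    out_dim = math.ceil(dim / stride)
    pad = max((out_dim - 1) * stride + k - dim, 0)
    return out_dim, pad // 2, pad - pad // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """2-D convolution, NHWC layout, SAME padding with ceil output sizes.

    ``x`` is (N, H, W, Cin); ``w`` is (kh, kw, Cin, Cout); output spatial dims
    are ``ceil(H/stride) x ceil(W/stride)``.  im2col + one GEMM; the column
    matrix is kept for the backward pass.
    """
    N, H, W, Cin = x.data.shape
    kh, kw, Cin2, Cout = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"conv2d channel mismatch: input {Cin}, kernel {Cin2}")
    Ho, ph0, ph1 = _same_ceil_pad(H, stride, kh)
    Wo, pw0, pw1 = _same_ceil_pad(W, stride, kw)
    xp = np.pad(x.data, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))

    # im2col: (N*Ho*Wo, kh*kw*Cin), tap index between spatial and channel axes
    # so a plain reshape lines up with w.reshape(-1, Cout)
    cols = np.empty((N, Ho, Wo, kh * kw, Cin), dtype=_F32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i * kw + j, :] = xp[
                :, i : i + stride * Ho : stride, j : j + stride * Wo : stride, :
            ]
    cols2 = cols.reshape(N * Ho * Wo, kh * kw * Cin)
    out_data = cols2 @ w.data.reshape(-1, Cout)
    out_data = out_data.reshape(N, Ho, Wo, Cout)
    if b is not None:
        out_data += b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward():
        g2 = out.grad.reshape(-1, Cout)  # (N*Ho*Wo, Cout)
        if w.requires_grad:
            w._accum((cols2.T @ g2).reshape(kh, kw, Cin, Cout))
        if x.requires_grad:
            dcols = (g2 @ w.data.reshape(-1, Cout).T).reshape(N, Ho, Wo, kh * kw, Cin)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i : i + stride * Ho : stride, j : j + stride * Wo : stride, :] += dcols[
                        :, :, :, i * kw + j, :
                    ]
            x._accum(np.ascontiguousarray(gxp[:, ph0 : ph0 + H, pw0 : pw0 + W, :]))
        if b is not None and b.requires_grad:
            b._accum(out.grad.sum(axis=(0, 1, 2)))

    out = Tensor._make(out_data, parents, backward)
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch normalization over axes (0, 1, 2) of NHWC.

    Returns the normalized tensor plus the batch mean and (biased) variance
    per channel, so the caller can maintain running statistics.
    """
    axes = (0, 1, 2)
    mu = x.data.mean(axis=axes)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=axes)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gamma.data * xhat + beta.data

    def backward():
        g = out.grad
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data
            m = dxhat.mean(axis=axes)
            mx = (dxhat * xhat).mean(axis=axes)
            x._accum(((dxhat - m - xhat * mx) * inv).astype(_F32))

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out, mu, var


def upsample2x(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Nearest-neighbour 2x up-sampling of (N, H, W, C), cropped to (out_h, out_w)."""
    N, H, W, C = x.data.shape
    if out_h > 2 * H or out_w > 2 * W:
        raise ValueError("upsample2x can only crop, not pad")
    up = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    out_data = up[:, :out_h, :out_w, :]

    def backward():
        if x.requires_grad:
            g = np.zeros((N, 2 * H, 2 * W, C), dtype=_F32)
            g[:, :out_h, :out_w, :] = out.grad
            x._accum(g.reshape(N, H, 2, W, 2, C).sum(axis=(2, 4)))

    out = Tensor._make(out_data, (x,), backward)
    return out
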