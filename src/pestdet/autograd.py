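"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the detection networks need: broadcasted
arithmetic, the usual nonlinearities, reductions, indexing, concatenation and
shape ops.  Convolution/pooling live in :mod:`pestdet.nn` as fused primitives
with hand-written adjoints.  All tensors are float32.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit

__all__ = ["Tensor", "concat", "maximum", "minimum", "softplus", "silu", "ts",
           "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._parents = parents if self.requires_grad or parents else ()
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._node(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, out):
            if self.requires_grad:
                self._accum(-g)

        return self._node(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._node(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def bw(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data * other.data), other.data.shape)
                )

        return self._node(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g, out):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._node(out_data, (self,), bw)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g * out.data)

        return self._node(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._node(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g * (1.0 - out.data * out.data))

        return self._node(out_data, (self,), bw)

    def sigmoid(self):
        out_data = _expit(self.data)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g * out.data * (1.0 - out.data))

        return self._node(out_data, (self,), bw)

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(np.float32))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).astype(np.float32))

        return self._node(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        return self._node(out_data, (self,), bw)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bw(g, out):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._node(out_data, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g, out):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._node(out_data, (self,), bw)

    # -- backward engine ------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad, t)
                if t._parents:
                    t.grad = None  # free intermediate grads


def maximum(a, b) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = np.maximum(a.data, b.data)

    def bw(g, out):
        mask = (a.data >= b.data).astype(np.float32)
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (1.0 - mask), b.data.shape))

    return Tensor._node(out_data, (a, b), bw)


def minimum(a, b) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = np.minimum(a.data, b.data)

    def bw(g, out):
        mask = (a.data <= b.data).astype(np.float32)
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (1.0 - mask), b.data.shape))

    return Tensor._node(out_data, (a, b), bw)


def softplus(x: Tensor) -> Tensor:
    """Numerically stable log(1 + e^x) = max(x, 0) + log1p(e^(-|x|))."""
    x = Tensor._lift(x)
    out_data = (np.maximum(x.data, 0.0) + np.log1p(np.exp(-np.abs(x.data)))).astype(np.float32)

    def bw(g, out):
        if x.requires_grad:
            x._accum(g * _expit(x.data))

    return Tensor._node(out_data, (x,), bw)


def silu(x: Tensor) -> Tensor:
    """Fused SiLU: x * sigmoid(x)."""
    s = _expit(x.data)
    out_data = x.data * s

    def bw(g, out):
        if x.requires_grad:
            x._accum(g * (s * (1.0 + x.data * (1.0 - s))))

    return Tensor._node(out_data, (x,), bw)


def ts(x: Tensor) -> Tensor:
    """Fused Tanh-Softplus: tanh(x) * log(1 + e^x) (stable softplus)."""
    th = np.tanh(x.data)
    sp = (np.maximum(x.data, 0.0) + np.log1p(np.exp(-np.abs(x.data)))).astype(np.float32)
    out_data = th * sp

    def bw(g, out):
        if x.requires_grad:
            x._accum(g * ((1.0 - th * th) * sp + th * _expit(x.data)))

    return Tensor._node(out_data, (x,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, out):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._node(out_data, tuple(tensors), bw)
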