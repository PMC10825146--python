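"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the compute engine behind the translation framework: a small tape-based
``Tensor`` supporting the operations the encoders/decoders, discriminators,
losses and integrated-gradient attribution need.  Gradients follow the usual
vector-Jacobian-product rules; broadcasting is handled by summing gradients
over broadcast axes.  Everything is float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln as _gammaln, psi as _psi

__all__ = ["Tensor", "cat", "logsumexp", "softplus", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED[0]
        self.grad = None
        self._backward = None
        self._prev: tuple = ()

    # ---- graph plumbing -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = _GRAD_ENABLED[0] and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self):
        self.grad = None

    # ---- conveniences ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T if other.data.ndim > 1 else np.outer(g, other.data))
            if other.requires_grad:
                other._accum(self.data.T @ g if self.data.ndim > 1 else np.outer(self.data, g))

        return Tensor._make(out_data, (self, other), backward)

    @property
    def T(self):
        def backward(g):
            self._accum(g.T)

        return Tensor._make(self.data.T, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # ---- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def backward(g):
            self._accum(g * np.where(mask, 1.0, slope))

        return Tensor._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        em1 = alpha * np.expm1(np.minimum(self.data, 0.0))
        out_data = np.where(pos, self.data, em1)

        def backward(g):
            self._accum(g * np.where(pos, 1.0, em1 + alpha))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        # stable branch form: softplus(x) = max(x, 0) + log1p(exp(-|x|))
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            self._accum(g * sig)

        return Tensor._make(out_data, (self,), backward)

    def lgamma(self):
        out_data = _gammaln(self.data)

        def backward(g):
            self._accum(g * _psi(self.data))

        return Tensor._make(out_data, (self,), backward)


def cat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis, with gradient routing."""
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def softplus(x):
    """Numerically stable softplus on Tensors or plain arrays."""
    if isinstance(x, Tensor):
        return x.softplus()
    x = np.asarray(x, dtype=np.float64)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """log-sum-exp with the max subtracted as a constant (a.e. exact gradient)."""
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        out = out.reshape(np.squeeze(out.data, axis=axis).shape)
    return out
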