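"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's composite training objective (distribution-moment losses,
cosine-orthogonality penalties, hinged contrastive terms, attention and gated
fusion) needs gradients through arbitrary compositions of array operations.
This module provides a small, vectorised tape: a :class:`Tensor` wraps a
float64 ndarray, records its parents, and `backward()` runs reverse-mode
accumulation over the topologically sorted graph.

Only the operations the model uses are implemented. Broadcasting follows
numpy semantics; gradients of broadcast operands are summed back to the
operand's shape. All data is float64 for run-to-run determinism on CPU.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "cat", "stack", "sqrt", "absolute"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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
    """A float64 array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents: tuple, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Reverse-mode accumulation from this (typically scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS: the loss graphs here can be a few thousand nodes deep
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._prev if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            a._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bw(g, a=self):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
            b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            a._accum(g * o)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g, a=self):
            a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g, a=self, o=out_data):
            a._accum(g * (1.0 - o**2))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g, a=self, o=out_data):
            a._accum(g * o * (1.0 - o))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g, a=self, m=mask):
            a._accum(g * m)

        return Tensor._make(self.data * mask, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g, a=self, o=out_data):
            # clamp the denominator: subgradient 0 at exactly 0 would be inf
            a._accum(g / (2.0 * np.maximum(o, 1e-12)))

        return Tensor._make(out_data, (self,), bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g, a=self, s=sign):
            a._accum(g * s)

        return Tensor._make(np.abs(self.data), (self,), bw)

    __abs__ = abs

    def clip_min(self, lo: float):
        """max(self, lo) with a constant floor (gradient 0 below the floor)."""
        mask = self.data > lo

        def bw(g, a=self, m=mask):
            a._accum(g * m)

        return Tensor._make(np.maximum(self.data, lo), (self,), bw)

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g, a=self):
            a._accum(g.reshape(a.data.shape))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def swapaxes(self, a1: int, a2: int):
        def bw(g, a=self):
            a._accum(np.swapaxes(g, a1, a2))

        return Tensor._make(np.swapaxes(self.data, a1, a2), (self,), bw)

    def take(self, indices, axis: int = 0):
        """Gather along `axis` with integer indices (rows may repeat)."""
        indices = np.asarray(indices)

        def bw(g, a=self, idx=indices, ax=axis):
            full = np.zeros_like(a.data)
            if ax == 0:
                np.add.at(full, idx, g)
            else:  # pragma: no cover - only axis 0 used by the model
                moved = np.moveaxis(full, ax, 0)
                np.add.at(moved, idx, np.moveaxis(g, ax, 0))
            a._accum(full)

        return Tensor._make(np.take(self.data, indices, axis=axis), (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def cat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def sqrt(x):
    """Dispatching sqrt: works on Tensors and plain arrays/scalars."""
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def absolute(x):
    """Dispatching absolute value for Tensors and plain arrays/scalars."""
    return x.abs() if isinstance(x, Tensor) else np.abs(x)
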