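"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine sized for the desk-scale volumetric
networks in this package.  Every :class:`Tensor` wraps a float32 ndarray;
operations record a backward closure, and :meth:`Tensor.backward` runs the
tape in reverse topological order.  Gradients with respect to network inputs
(needed for saliency maps) fall out of the same mechanism as parameter
gradients.

Only the operations the package actually uses are provided: elementwise
arithmetic with broadcasting, matmul, reductions, slicing/reshaping, the
stable log-sigmoid used by the cross-entropy loss, and elementwise min/max
(for differentiable box-overlap geometry).  Convolution, pooling, batch
normalisation and dropout live in :mod:`meniscus3d.nn` as custom primitives
built on the same Tensor class.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "concatenate", "stack",
           "default_dtype", "using_dtype"]

_GRAD_ENABLED = [True]
_DTYPE = [np.float32]


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def default_dtype():
    return _DTYPE[-1]


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape construction (eval-mode forward)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


@contextlib.contextmanager
def using_dtype(dtype):
    """Temporarily change the engine's working precision.

    Training runs in float32; float64 is useful for verifying gradients
    against finite differences below the single-precision noise floor.
    Models must be *built* inside the context to carry the dtype.
    """
    _DTYPE.append(np.dtype(dtype).type)
    try:
        yield
    finally:
        _DTYPE.pop()


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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE[-1])
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def make(data, parents: Iterable["Tensor"], backward) -> "Tensor":
        """Create an op output; records the tape edge only when tracking."""
        parents = tuple(parents)
        track = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = parents
            out._backward = backward
        return out

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- basic info -----------------------------------------------------------
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

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs are deep for 50-layer nets)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p._parents]
            pending = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                for p in pending:
                    seen.add(id(p))
                    topo.append(p)
                topo.append(node)
                stack.pop()
        # de-duplicate while keeping order (leaves may appear once already)
        order: list[Tensor] = []
        placed: set[int] = set()
        for node in topo:
            if id(node) not in placed:
                placed.add(id(node))
                order.append(node)
        self.accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node is not self:
                    node.grad = None  # free intermediate grads eagerly

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a.accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(g, b.data.shape))

        return Tensor.make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor.make(-a.data, (a,), lambda g: a.accumulate(-g))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a.accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor.make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a.accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor.make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p
        return Tensor.make(out_data, (a,), lambda g: a.accumulate(g * p * a.data ** (p - 1)))

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor.make(out_data, (a,), lambda g: a.accumulate(g * out_data))

    def log(self):
        a = self
        return Tensor.make(np.log(a.data), (a,), lambda g: a.accumulate(g / a.data))

    def abs(self):
        a = self
        return Tensor.make(np.abs(a.data), (a,), lambda g: a.accumulate(g * np.sign(a.data)))

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a.accumulate(g * mask)

        return Tensor.make(a.data * mask, (a,), bwd)

    def sigmoid(self):
        a = self
        s = _sigmoid(a.data)
        return Tensor.make(s, (a,), lambda g: a.accumulate(g * s * (1.0 - s)))

    def logsigmoid(self):
        """log(sigmoid(x)) computed as -softplus(-x), numerically stable."""
        a = self
        out_data = -_softplus(-a.data)
        return Tensor.make(out_data, (a,), lambda g: a.accumulate(g * _sigmoid(-a.data)))

    def maximum(self, other):
        other = Tensor._lift(other)
        a, b = self, other
        mask = a.data >= b.data  # ties route the gradient to the first argument

        def bwd(g):
            if a.requires_grad:
                a.accumulate(_unbroadcast(g * mask, a.data.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(g * (~mask), b.data.shape))

        return Tensor.make(np.maximum(a.data, b.data), (a, b), bwd)

    def minimum(self, other):
        other = Tensor._lift(other)
        a, b = self, other
        mask = a.data <= b.data

        def bwd(g):
            if a.requires_grad:
                a.accumulate(_unbroadcast(g * mask, a.data.shape))
            if b.requires_grad:
                b.accumulate(_unbroadcast(g * (~mask), b.data.shape))

        return Tensor.make(np.minimum(a.data, b.data), (a, b), bwd)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a.accumulate(np.broadcast_to(g, a.data.shape))

        return Tensor.make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        n = a.data.size if axis is None else np.prod(
            [a.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
        )

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a.accumulate(np.broadcast_to(g, a.data.shape) / n)

        return Tensor.make(a.data.mean(axis=axis, keepdims=keepdims), (a,), bwd)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor.make(a.data.reshape(shape), (a,), lambda g: a.accumulate(g.reshape(old)))

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor.make(
            np.ascontiguousarray(a.data.transpose(axes)), (a,),
            lambda g: a.accumulate(g.transpose(tuple(inv))),
        )

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a.accumulate(full)

        return Tensor.make(a.data[idx], (a,), bwd)

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a.accumulate(g @ b.data.T)
            if b.requires_grad:
                b.accumulate(a.data.T @ g)

        return Tensor.make(a.data @ b.data, (a, b), bwd)

    __matmul__ = matmul


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def concatenate(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    return Tensor.make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)


def stack(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t.accumulate(np.take(g, i, axis=axis))

    return Tensor.make(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)
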