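"""Minimal reverse-mode automatic differentiation over numpy arrays.

The differentiable breeding scheme needs gradients of a scalar merit with
respect to a handful of allocation parameters, through a computation built
from dense array arithmetic, softmaxes and constant-index gathers.  This
module provides exactly that: a :class:`Tensor` wrapping an ``ndarray``
together with reverse-mode backpropagation over the operations the scheme
uses.  Discrete quantities (segregation indicators, ranking index sets) enter
the graph as constants, so every recorded operation is smooth in its real
inputs.

Most helpers here (``exp``, ``log``, ``clip_min`` ...) dispatch on type: they
accept either a Tensor or a plain ndarray and return the matching kind, which
lets the same metric formulas serve the soft (in-graph) and hard (discrete)
simulation paths.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "stack",
    "exp",
    "log",
    "sqrt",
    "power",
    "sigmoid",
    "clip_min",
    "minimum2",
    "softmax_last",
    "take_flat",
    "take_rows",
    "is_tensor",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in a reverse-mode differentiation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    # make numpy defer to the reflected Tensor operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward_fn = backward_fn

    # ------------------------------------------------------------------
    # introspection
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------------
    # graph construction helpers
    @staticmethod
    def _make(data, parents, backward_fn) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=parents, backward_fn=backward_fn)

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        o = as_tensor(other)
        out_data = self.data + o.data
        a_shape, b_shape = self.data.shape, o.data.shape

        def bw(g):
            return _unbroadcast(g, a_shape), _unbroadcast(g, b_shape)

        return Tensor._make(out_data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        o = as_tensor(other)
        a, b = self.data, o.data

        def bw(g):
            return _unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)

        return Tensor._make(a * b, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        a, b = self.data, o.data

        def bw(g):
            return (
                _unbroadcast(g / b, a.shape),
                _unbroadcast(-g * a / (b * b), b.shape),
            )

        return Tensor._make(a / b, (self, o), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):  # pragma: no cover - not needed
            raise TypeError("tensor exponents are not supported")
        a = self.data

        def bw(g):
            return (g * exponent * np.power(a, exponent - 1.0),)

        return Tensor._make(np.power(a, exponent), (self,), bw)

    def __matmul__(self, other):
        o = as_tensor(other)
        a, b = self.data, o.data
        out = a @ b

        def bw(g):
            g = np.asarray(g)
            if b.ndim == 1 and a.ndim == 1:
                return g * b, g * a
            if b.ndim == 1:
                return np.outer(g, b) if a.ndim == 2 else g[..., None] * b, a.T @ g if a.ndim == 2 else np.tensordot(g, a, axes=a.ndim - 1)
            if a.ndim == 1:
                return g @ b.T, np.outer(a, g)
            return g @ np.swapaxes(b, -1, -2), np.swapaxes(a, -1, -2) @ g

        return Tensor._make(out, (self, o), bw)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # ------------------------------------------------------------------
    # reductions & shaping
    def sum(self, axis=None, keepdims: bool = False):
        a_shape = self.data.shape
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, a_shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for a in sorted(a_ % len(a_shape) for a_ in ax):
                    g = np.expand_dims(g, a)
            return (np.broadcast_to(g, a_shape).copy(),)

        return Tensor._make(out, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a_shape = self.data.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(a_shape),)
        )

    def __getitem__(self, key):
        """Constant-index selection (slices or integer arrays)."""
        a_shape = self.data.shape
        out = self.data[key]

        def bw(g):
            full = np.zeros(a_shape, dtype=np.float64)
            np.add.at(full, key, g)
            return (full,)

        return Tensor._make(out, (self,), bw)

    # ------------------------------------------------------------------
    # backward pass
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS with explicit post-order to avoid recursion limits
        post: list[tuple[Tensor, bool]] = [(self, False)]
        while post:
            node, processed = post.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            post.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    post.append((p, False))
        del stack_

        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            parent_grads = node._backward_fn(node.grad)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                pg = np.asarray(pg, dtype=np.float64)
                if p.grad is None:
                    p.grad = pg
                else:
                    p.grad = p.grad + pg

    def zero_grad(self) -> None:
        self.grad = None


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------------
# dispatching element-wise helpers (Tensor in -> Tensor out, array -> array)

def exp(x):
    if isinstance(x, Tensor):
        out = np.exp(x.data)
        return Tensor._make(out, (x,), lambda g: (g * out,))
    return np.exp(x)


def log(x):
    if isinstance(x, Tensor):
        a = x.data
        return Tensor._make(np.log(a), (x,), lambda g: (g / a,))
    return np.log(x)


def sqrt(x):
    if isinstance(x, Tensor):
        out = np.sqrt(x.data)
        return Tensor._make(out, (x,), lambda g: (g * 0.5 / out,))
    return np.sqrt(x)


def power(x, p: float):
    if isinstance(x, Tensor):
        return x ** p
    return np.power(x, p)


def sigmoid(x):
    if isinstance(x, Tensor):
        out = 1.0 / (1.0 + np.exp(-x.data))
        return Tensor._make(out, (x,), lambda g: (g * out * (1.0 - out),))
    return 1.0 / (1.0 + np.exp(-x))


def clip_min(x, lo: float):
    """max(x, lo) element-wise; gradient flows where x > lo."""
    if isinstance(x, Tensor):
        mask = (x.data > lo).astype(np.float64)
        out = np.maximum(x.data, lo)
        return Tensor._make(out, (x,), lambda g: (g * mask,))
    return np.maximum(x, lo)


def minimum2(a, b):
    """Element-wise minimum of two same-kind operands (ties go to ``a``)."""
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        at, bt = as_tensor(a), as_tensor(b)
        mask = (at.data <= bt.data).astype(np.float64)
        out = np.minimum(at.data, bt.data)

        def bw(g):
            return (
                _unbroadcast(g * mask, at.data.shape),
                _unbroadcast(g * (1.0 - mask), bt.data.shape),
            )

        return Tensor._make(out, (at, bt), bw)
    return np.minimum(a, b)


def concatenate(parts, axis: int = 0):
    if any(isinstance(p, Tensor) for p in parts):
        ts = [as_tensor(p) for p in parts]
        sizes = [t.data.shape[axis] for t in ts]
        out = np.concatenate([t.data for t in ts], axis=axis)
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            return tuple(np.split(g, splits, axis=axis))

        return Tensor._make(out, tuple(ts), bw)
    return np.concatenate(parts, axis=axis)


def stack(parts, axis: int = 0):
    if any(isinstance(p, Tensor) for p in parts):
        ts = [as_tensor(p) for p in parts]
        out = np.stack([t.data for t in ts], axis=axis)

        def bw(g):
            return tuple(np.moveaxis(g, axis, 0))

        return Tensor._make(out, tuple(ts), bw)
    return np.stack(parts, axis=axis)


def softmax_last(x):
    """Softmax along the last axis with max-subtraction for stability.

    The subtracted maximum is treated as a constant shift, which leaves both
    the value and the derivative of the softmax unchanged.
    """
    if isinstance(x, Tensor):
        shift = x.data.max(axis=-1, keepdims=True)
        e = exp(x - shift)
        return e / e.sum(axis=-1, keepdims=True)
    shift = x.max(axis=-1, keepdims=True)
    e = np.exp(x - shift)
    return e / e.sum(axis=-1, keepdims=True)


def take_flat(x, flat_index: np.ndarray):
    """Gather from the flattened ``x`` with a constant integer index array.

    The backward pass scatter-adds through ``np.bincount``, which keeps the
    per-generation candidate construction (millions of gathered elements)
    fast.
    """
    flat_index = np.asarray(flat_index)
    if isinstance(x, Tensor):
        flat = x.data.reshape(-1)
        out = flat[flat_index]
        size = flat.size
        a_shape = x.data.shape

        def bw(g):
            acc = np.bincount(
                flat_index.ravel(), weights=np.asarray(g, dtype=np.float64).ravel(),
                minlength=size,
            )
            return (acc.reshape(a_shape),)

        return Tensor._make(out, (x,), bw)
    return np.asarray(x).reshape(-1)[flat_index]


def take_rows(x, row_index):
    """Select rows by a constant integer index (works on both kinds)."""
    row_index = np.asarray(row_index, dtype=np.intp)
    if isinstance(x, Tensor):
        return x[row_index]
    return np.asarray(x)[row_index]
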