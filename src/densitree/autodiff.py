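"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed to train a fully connected
autoencoder under the tree-bias losses: dense affine maps, ReLU,
elementwise arithmetic, reductions, row gathering and per-cluster
(segment) means.  Gradients flow through segment means, which is how the
embedding-space centroids — means of embedded points — receive gradient.

Values are kept in float64; graphs are rebuilt on every forward pass.
"""

from __future__ import annotations

from typing import Callable, List, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "constant", "matmul", "relu", "gather_rows", "segment_mean"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over broadcast axes so it matches ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    value
        The forward value, converted to a float64 ndarray.
    parents
        Sequence of ``(parent, vjp)`` pairs where ``vjp`` maps the output
        gradient to the gradient contribution for ``parent``.
    """

    __slots__ = ("value", "grad", "parents")

    def __init__(self, value, parents: Sequence[Tuple["Tensor", Callable]] = ()):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)

    @property
    def shape(self):
        return self.value.shape

    # -- graph traversal ------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the graph."""
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        order: List[Tensor] = []
        seen: set[int] = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS post-order; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node.parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node.grad is None:
                continue
            for parent, vjp in node.parents:
                contribution = vjp(node.grad)
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.value)
                parent.grad = parent.grad + contribution

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -----------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.value + other.value,
            [
                (self, lambda g: _unbroadcast(g, self.value.shape)),
                (other, lambda g: _unbroadcast(g, other.value.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.value * other.value,
            [
                (self, lambda g: _unbroadcast(g * other.value, self.value.shape)),
                (other, lambda g: _unbroadcast(g * self.value, other.value.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.value / other.value,
            [
                (self, lambda g: _unbroadcast(g / other.value, self.value.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.value / other.value**2, other.value.shape
                    ),
                ),
            ],
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor(
            self.value**exponent,
            [(self, lambda g: g * exponent * self.value ** (exponent - 1))],
        )

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None):
        value = self.value.sum(axis=axis)

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.value.shape).copy()
            return np.broadcast_to(
                np.expand_dims(g, axis), self.value.shape
            ).copy()

        return Tensor(value, [(self, vjp)])

    def mean(self, axis=None):
        count = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis) * (1.0 / count)

    # -- unary maps ------------------------------------------------------
    def sqrt(self):
        root = np.sqrt(self.value)
        return Tensor(root, [(self, lambda g: g * 0.5 / root)])

    def clip_min(self, floor: float):
        """max(x, floor); the gradient is blocked where the floor binds."""
        mask = self.value > floor
        return Tensor(np.maximum(self.value, floor), [(self, lambda g: g * mask)])


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """Wrap an array as a leaf node (no gradient is requested of leaves)."""
    return Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.value @ b.value,
        [
            (a, lambda g: g @ b.value.T),
            (b, lambda g: a.value.T @ g),
        ],
    )


def relu(x: Tensor) -> Tensor:
    mask = x.value > 0
    return Tensor(x.value * mask, [(x, lambda g: g * mask)])


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]``; the adjoint scatter-adds back."""
    index = np.asarray(index, dtype=np.intp)

    def vjp(g):
        out = np.zeros_like(x.value)
        np.add.at(out, index, g)
        return out

    return Tensor(x.value[index], [(x, vjp)])


def segment_mean(x: Tensor, labels: np.ndarray, n_segments: int) -> Tensor:
    """Per-segment mean of rows of ``x``; every segment must be non-empty.

    This is the differentiable path from embedded points to embedding-space
    centroids: each centroid is the arithmetic mean of its cluster's rows,
    and the adjoint distributes the centroid gradient back uniformly.
    """
    labels = np.asarray(labels, dtype=np.intp)
    counts = np.bincount(labels, minlength=n_segments)
    if np.any(counts == 0):
        raise ValueError("segment_mean requires every segment to be non-empty")
    sums = np.zeros((n_segments, x.value.shape[1]))
    np.add.at(sums, labels, x.value)
    means = sums / counts[:, None]

    def vjp(g):
        return g[labels] / counts[labels, None]

    return Tensor(means, [(x, vjp)])
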