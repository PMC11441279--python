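"""Minimal reverse-mode automatic differentiation over numpy float64 arrays.

Supports exactly the operations the package's neural modules need: broadcasted
arithmetic, matrix products, the activation functions, reductions,
concatenation, a numerically stable binary cross entropy on logits, and a
masked row-wise softmax for graph attention.  Everything is deterministic and
double precision, which keeps seeded training runs bit-reproducible and makes
finite-difference gradient checks tight.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "masked_softmax",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, _parents: tuple["Tensor", ...] = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward: Callable[[], None] = lambda: None

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            node._backward()

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def _backward():
            self._accumulate(out.grad)
            other._accumulate(out.grad)

        out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, (self,))
        out._backward = lambda: self._accumulate(-out.grad)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def _backward():
            self._accumulate(out.grad * other.data)
            other._accumulate(out.grad * self.data)

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data / other.data, (self, other))

        def _backward():
            self._accumulate(out.grad / other.data)
            other._accumulate(-out.grad * self.data / other.data**2)

        out._backward = _backward
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, (self,))
        out._backward = lambda: self._accumulate(
            out.grad * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def _backward():
            self._accumulate(out.grad @ other.data.T)
            other._accumulate(self.data.T @ out.grad)

        out._backward = _backward
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, (self,))
        out._backward = lambda: self._accumulate(out.grad.T)
        return out

    # -- reductions --------------------------------------------------------

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), (self,))
        out._backward = lambda: self._accumulate(
            np.broadcast_to(out.grad, self.data.shape)
        )
        return out

    def mean(self, axis: int | None = None) -> "Tensor":
        out = Tensor(self.data.mean(axis=axis), (self,))
        n = self.data.size if axis is None else self.data.shape[axis]

        def _backward():
            g = out.grad / n
            if axis is not None:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = _backward
        return out

    def row_sum_mean(self) -> "Tensor":
        """Mean over rows of the per-row sum (Eq-16 style reduction)."""
        return self.sum() * (1.0 / self.data.shape[0])

    # -- activations -------------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda: self._accumulate(out.grad * (self.data > 0))
        return out

    def leaky_relu(self, negative_slope: float = 0.2) -> "Tensor":
        y = np.where(self.data > 0, self.data, negative_slope * self.data)
        out = Tensor(y, (self,))
        out._backward = lambda: self._accumulate(
            out.grad * np.where(self.data > 0, 1.0, negative_slope)
        )
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        y = np.where(self.data > 0, self.data, alpha * np.expm1(self.data))
        out = Tensor(y, (self,))
        out._backward = lambda: self._accumulate(
            out.grad * np.where(self.data > 0, 1.0, y + alpha)
        )
        return out

    def sigmoid(self) -> "Tensor":
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        out = Tensor(y, (self,))
        out._backward = lambda: self._accumulate(out.grad * y * (1.0 - y))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda: self._accumulate(out.grad * y)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda: self._accumulate(out.grad / self.data)
        return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out.data.ndim
            idx[axis] = slice(a, b)
            t._accumulate(out.grad[tuple(idx)])

    out._backward = _backward
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to positions where ``mask`` is nonzero.

    Rows must have at least one unmasked position (guaranteed by self-loops in
    the graph modules).  Masked positions get exactly 0.
    """
    m = np.asarray(mask, dtype=bool)
    x = np.where(m, scores.data, -np.inf)
    x_max = x.max(axis=-1, keepdims=True)
    ex = np.exp(x - x_max)
    ex = np.where(m, ex, 0.0)
    denom = ex.sum(axis=-1, keepdims=True)
    alpha = ex / denom
    out = Tensor(alpha, (scores,))

    def _backward():
        g = out.grad
        dot = (g * alpha).sum(axis=-1, keepdims=True)
        scores._accumulate(alpha * (g - dot))

    out._backward = _backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Element-wise binary cross entropy on logits (numerically stable)."""
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss, (logits,))

    def _backward():
        sig = 0.5 * (1.0 + np.tanh(0.5 * z))
        logits._accumulate(out.grad * (sig - y))

    out._backward = _backward
    return out
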