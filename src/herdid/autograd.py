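"""Minimal reverse-mode automatic differentiation over numpy arrays.

The embedding head and the dual metric-learning loss need gradients with
respect to dense parameters (linear layers, batch-norm affine terms, the
sub-center weight bank and the class centers).  This module provides a small
tape-based engine in the micrograd style: a :class:`Tensor` wraps a float64
ndarray, records its parents, and ``backward()`` walks the graph in reverse
topological order accumulating gradients.  Broadcasting follows numpy rules;
gradients of broadcast operands are summed back to the original shape.

Only the operations the package needs are implemented.  Correctness is
guarded by finite-difference tests (``tests/test_autograd.py``).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # remove prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    data:
        Array-like payload; stored as float64.
    requires_grad:
        Whether gradients should be accumulated into ``self.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Iterable["Tensor"] = (),
                 _backward: Callable[[], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents)
        self._backward = _backward or (lambda: None)

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd():
            self._accum(out.grad)
            other._accum(out.grad)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bwd():
            self._accum(-out.grad)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd():
            self._accum(out.grad * other.data)
            other._accum(out.grad * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd():
            self._accum(out.grad / other.data)
            other._accum(-out.grad * self.data / other.data ** 2)
        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))

        def bwd():
            self._accum(out.grad * exponent * self.data ** (exponent - 1))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)
        out._backward = bwd
        return out

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def bwd():
            self._accum(out.grad * out.data)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bwd():
            self._accum(out.grad / self.data)
        out._backward = bwd
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))

        def bwd():
            self._accum(out.grad * 0.5 / np.maximum(out.data, 1e-300))
        out._backward = bwd
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def bwd():
            self._accum(out.grad * (self.data > 0))
        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclamped entries."""
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        mask = (self.data > lo) & (self.data < hi)

        def bwd():
            self._accum(out.grad * mask)
        out._backward = bwd
        return out

    # -- reductions and shape ops ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bwd():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along an axis; ties share the gradient equally."""
        maxval = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == maxval)
        mask = mask / mask.sum(axis=axis, keepdims=True)
        out = Tensor(maxval if keepdims else maxval.squeeze(axis),
                     _parents=(self,))

        def bwd():
            g = out.grad if keepdims else np.expand_dims(out.grad, axis)
            self._accum(g * mask)
        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bwd():
            self._accum(out.grad.reshape(self.data.shape))
        out._backward = bwd
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _parents=(self,))

        def bwd():
            self._accum(out.grad.T)
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        """Gather; supports integer-array row indexing (scatter-add backward)."""
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)
        out._backward = bwd
        return out

    # -- graph traversal ------------------------------------------------------

    def backward(self) -> None:
        """Accumulate gradients of this (scalar or array, seeded with ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            node._backward()

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat_rows(tensors: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 0."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0),
                 _parents=tuple(tensors))
    offsets = np.cumsum([0] + [t.data.shape[0] for t in tensors])

    def bwd():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            t._accum(out.grad[a:b])
    out._backward = bwd
    return out
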