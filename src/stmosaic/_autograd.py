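"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (two dense layers, three graph
convolutions, a handful of scalar losses) and is trained full-batch on
desk-scale data, so a compact tape-based engine over float64 numpy arrays
is sufficient and keeps the dependency footprint to numpy/scipy only.

Only the operations actually used by the model are implemented.  Sparse
matrices (the normalized adjacency) participate as constants on the left
of ``spmm``; gradients never flow into them.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Parameter", "spmm", "relu", "sigmoid", "exp", "log", "sqrt", "maximum0"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        def backward(g, out):
            return (g.T,)

        return self._make(self.data.T, (self,), backward)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            return (-g,)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g, out):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    def __getitem__(self, idx):
        def backward(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff -------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A tensor that is updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- free functions -----------------------------------------------------------

def spmm(A: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse constant matrix times dense tensor: ``A @ x``."""
    A = A.tocsr()

    def backward(g, out):
        return (A.T @ g,)

    out = Tensor(A @ x.data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g, out):
        return (g * mask,)

    return x._make(np.where(mask, x.data, 0.0), (x,), backward)


maximum0 = relu


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def backward(g, out):
        return (g * s * (1.0 - s),)

    return x._make(s, (x,), backward)


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)

    def backward(g, out):
        return (g * e,)

    return x._make(e, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g, out):
        return (g / x.data,)

    return x._make(np.log(x.data), (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)

    def backward(g, out):
        return (g * 0.5 / r,)

    return x._make(r, (x,), backward)
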