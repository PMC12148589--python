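"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the projection network needs: broadcasted
add/mul, matmul, reshape/swapaxes, reductions, constant powers, softmax,
exact (erf-based) GELU and layer normalisation.  Gradients are accumulated
by reverse topological traversal; broadcasting is undone by summing over
broadcast axes.  Everything is float64 so the whole backward pass can be
validated against central finite differences to ~1e-6 relative error.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "softmax", "gelu", "layer_norm"]

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _backward: Callable[[np.ndarray], None] | None = None,
        _parents: tuple["Tensor", ...] = (),
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = _backward
        self._parents = _parents

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data + other.data
        need = self.requires_grad or other.requires_grad

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, need, bwd if need else None, (self, other))

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, self.requires_grad,
                      bwd if self.requires_grad else None, (self,))

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data * other.data
        need = self.requires_grad or other.requires_grad

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, need, bwd if need else None, (self, other))

    __rmul__ = __mul__

    def __pow__(self, exponent: float) -> "Tensor":
        if not isinstance(exponent, (int, float)):
            raise TypeError("only constant exponents are supported")
        out_data = self.data ** exponent

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, self.requires_grad,
                      bwd if self.requires_grad else None, (self,))

    # -- linear algebra / shape --------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out_data = self.data @ other.data
        need = self.requires_grad or other.requires_grad

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                if other.data.ndim == 1:
                    self._accumulate(_unbroadcast(np.multiply.outer(g, other.data),
                                                  self.shape))
                else:
                    self._accumulate(
                        _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accumulate(_unbroadcast(np.multiply.outer(self.data, g),
                                                   other.shape))
                else:
                    other._accumulate(
                        _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor(out_data, need, bwd if need else None, (self, other))

    __matmul__ = matmul

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape
        out_data = self.data.reshape(*shape)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor(out_data, self.requires_grad,
                      bwd if self.requires_grad else None, (self,))

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return Tensor(out_data, self.requires_grad,
                      bwd if self.requires_grad else None, (self,))

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        return Tensor(out_data, self.requires_grad,
                      bwd if self.requires_grad else None, (self,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    return Tensor(y, x.requires_grad, bwd if x.requires_grad else None, (x,))


def gelu(x: Tensor) -> Tensor:
    """Gaussian Error Linear Unit, exact erf form x·Φ(x)."""
    phi = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    y = x.data * phi

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
            x._accumulate(g * (phi + x.data * pdf))

    return Tensor(y, x.requires_grad, bwd if x.requires_grad else None, (x,))


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with learnable scale/shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    y = gamma.data * xhat + beta.data
    need = x.requires_grad or gamma.requires_grad or beta.requires_grad

    def bwd(g: np.ndarray) -> None:
        lead = tuple(range(g.ndim - 1))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=lead))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=lead))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    return Tensor(y, need, bwd if need else None, (x, gamma, beta))
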