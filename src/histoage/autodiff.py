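"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the slide-level regression network
needs: dense matmul, broadcast add/mul, ReLU, row softmax, reductions,
concatenation and elementwise power. Gradients are accumulated by
topological traversal of the (acyclic) expression graph.

Every operator's vector-Jacobian product is unit-tested against central
finite differences; see ``tests/test_autodiff.py``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad)
            if other.requires_grad:
                other._accum(out.grad)

        return Tensor(self.data + other.data, _parents=(self, other), _backward=backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accum(-out.grad)

        return Tensor(-self.data, _parents=(self,), _backward=backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * other.data)
            if other.requires_grad:
                other._accum(out.grad * self.data)

        return Tensor(self.data * other.data, _parents=(self, other), _backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by python scalars")
        return self * (1.0 / scalar)

    def __pow__(self, exponent: float):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        return Tensor(self.data ** exponent, _parents=(self,), _backward=backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def backward(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      _parents=(self,), _backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ----------------------------------------------------------------- shaping
    def reshape(self, *shape):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=backward)

    @property
    def T(self):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.T)

        return Tensor(self.data.T, _parents=(self,), _backward=backward)

    # ---------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                out_hold = node
                node._backward(out_hold)


# ------------------------------------------------------------------ functions
def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(out):
        if x.requires_grad:
            x._accum(out.grad * mask)

    return Tensor(x.data * mask, _parents=(x,), _backward=backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(out):
        if x.requires_grad:
            dot = (out.grad * s).sum(axis=axis, keepdims=True)
            x._accum(s * (out.grad - dot))

    return Tensor(s, _parents=(x,), _backward=backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis if axis >= 0 else out.grad.ndim + axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    return Tensor(np.concatenate(datas, axis=axis),
                  _parents=tuple(tensors), _backward=backward)
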