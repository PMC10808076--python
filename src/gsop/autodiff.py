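"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

The trainable components of this package are small multilayer perceptrons,
so a compact tape-based engine is sufficient: every operation records its
parents and a closure that accumulates the vector-Jacobian product into
them.  All arrays are float64.  Broadcasting follows numpy semantics; the
adjoint of a broadcast is a sum over the broadcast axes.

Design note: gradients of the learned potential with respect to its *input*
are expressed analytically as in-graph expressions (see ``gsop.core``), so a
single level of reverse-mode differentiation suffices for training losses
that contain those gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "parameter", "add", "sub", "mul", "div", "neg",
    "matmul", "tanh", "relu", "exp", "log", "sqrt", "square", "power",
    "tsum", "tmean", "reshape", "swap_last", "concat", "getitem", "maximum0",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep seeding ``self`` with ``grad`` (default ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = _as_array(grad)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS topological sort
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in order:
            node.grad = np.zeros_like(node.data)
        self.grad = grad
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def constant(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------- binary ops

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g, b.shape)

    out._backward = bw if out.requires_grad else None
    return out


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data - b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(-g, b.shape)

    out._backward = bw if out.requires_grad else None
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g * b.data, a.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * a.data, b.shape)

    out._backward = bw if out.requires_grad else None
    return out


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data / b.data, parents=(a, b))

    def bw(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g / b.data, a.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(-g * a.data / (b.data ** 2), b.shape)

    out._backward = bw if out.requires_grad else None
    return out


def neg(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(-a.data, parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad += -g

    out._backward = bw if out.requires_grad else None
    return out


def matmul(a, b) -> Tensor:
    """Matrix product with numpy stacking semantics (operands must be >= 2-D)."""
    a, b = _wrap(a), _wrap(b)
    out = Tensor(np.matmul(a.data, b.data), parents=(a, b))

    def bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a.grad += _unbroadcast(ga, a.shape)
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b.grad += _unbroadcast(gb, b.shape)

    out._backward = bw if out.requires_grad else None
    return out


# ----------------------------------------------------------------- unary ops

def tanh(a) -> Tensor:
    a = _wrap(a)
    y = np.tanh(a.data)
    out = Tensor(y, parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad += g * (1.0 - y * y)

    out._backward = bw if out.requires_grad else None
    return out


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad += g * mask

    out._backward = bw if out.requires_grad else None
    return out


maximum0 = relu  # alias: max(x, 0)


def exp(a) -> Tensor:
    a = _wrap(a)
    y = np.exp(a.data)
    out = Tensor(y, parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad += g * y

    out._backward = bw if out.requires_grad else None
    return out


def log(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.log(a.data), parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad += g / a.data

    out._backward = bw if out.requires_grad else None
    return out


def sqrt(a) -> Tensor:
    a = _wrap(a)
    y = np.sqrt(a.data)
    out = Tensor(y, parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad += g * 0.5 / y

    out._backward = bw if out.requires_grad else None
    return out


def square(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data * a.data, parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad += g * 2.0 * a.data

    out._backward = bw if out.requires_grad else None
    return out


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data ** p, parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad += g * p * a.data ** (p - 1.0)

    out._backward = bw if out.requires_grad else None
    return out


# ------------------------------------------------------------- reductions

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def bw(g):
        if not a.requires_grad:
            return
        gg = g
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.ndim for ax in axes)
            gg = np.expand_dims(gg, axes)
        a.grad += np.broadcast_to(gg, a.shape)

    out._backward = bw if out.requires_grad else None
    return out


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax % a.ndim] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


# ------------------------------------------------------------ shape ops

def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad += g.reshape(a.shape)

    out._backward = bw if out.requires_grad else None
    return out


def swap_last(a) -> Tensor:
    """Transpose the last two axes (batched matrix transpose)."""
    a = _wrap(a)
    out = Tensor(np.swapaxes(a.data, -1, -2), parents=(a,))

    def bw(g):
        if a.requires_grad:
            a.grad += np.swapaxes(g, -1, -2)

    out._backward = bw if out.requires_grad else None
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.grad += g[tuple(idx)]

    out._backward = bw if out.requires_grad else None
    return out


def getitem(a, idx) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data[idx], parents=(a,))

    def bw(g):
        if a.requires_grad:
            np.add.at(a.grad, idx, g)

    out._backward = bw if out.requires_grad else None
    return out
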