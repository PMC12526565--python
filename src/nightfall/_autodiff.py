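"""Minimal reverse-mode automatic differentiation over numpy arrays.

A deliberately small tensor/tape engine: enough operator coverage for the
recurrent and attention networks in :mod:`nightfall.nn` (broadcasting
arithmetic, matmul with batched operands, reductions, reshapes, slicing,
concatenation and the usual pointwise nonlinearities).  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`, which walks the
recorded graph in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "sigmoid", "tanh", "relu", "softmax", "log_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1.0),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._from_op(out_data, (self, other), backward)

    # -- pointwise nonlinearities ---------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,),
                               lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(out_data, (self,),
                               lambda g: (g * (1.0 - out_data ** 2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(out_data, (self,),
                               lambda g: (g * out_data * (1.0 - out_data),))

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        return Tensor._from_op(self.data.reshape(shape), (self,),
                               lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._from_op(self.data.transpose(axes), (self,),
                               lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs here can exceed recursion depth
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pg in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pg.copy() if isinstance(pg, np.ndarray) else np.asarray(pg)
                else:
                    parent.grad = parent.grad + pg

    def zero_grad(self):
        self.grad = None


# -- free functions ------------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            grads.append(g[tuple(sl)])
        return tuple(grads)

    return Tensor._from_op(out_data, tensors, backward)


def sigmoid(x: Tensor) -> Tensor:
    return Tensor._lift(x).sigmoid()


def tanh(x: Tensor) -> Tensor:
    return Tensor._lift(x).tanh()


def relu(x: Tensor) -> Tensor:
    return Tensor._lift(x).relu()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._lift(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._lift(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse
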