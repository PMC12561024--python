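"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, when gradients are
enabled, the operation that produced it.  Calling :meth:`Tensor.backward`
on a scalar walks the recorded graph in reverse topological order and
accumulates gradients into every tensor with ``requires_grad=True``.

Only the operations needed by the segmentation network and its losses are
implemented; shapes must match exactly for binary element-wise ops (the
layers broadcast biases internally).  All heavy kernels (convolution,
pooling, normalisation) live in :mod:`boneseg.nn.functional` as fused ops.
"""

from __future__ import annotations

import contextlib

import numpy as np

# module-level switch so inference can skip graph construction
_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
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
                if p._backward is not None or p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for p, g in zip(node._parents, grads):
                if g is None or not (p.requires_grad or p._backward is not None):
                    continue
                if p.grad is None:
                    p.grad = g
                else:
                    p.grad = p.grad + g
            # release graph references and intermediate gradients
            node._backward = None
            node._parents = ()
            node.grad = None

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_op(out_data, parents, backward_builder):
    """Create an op output.

    ``backward_builder`` is a zero-argument callable returning the backward
    closure; it is only invoked when a graph is actually being recorded, so
    ops can skip stashing intermediates during inference.
    """
    parents = tuple(as_tensor(p) for p in parents)
    if grad_enabled() and any(p.requires_grad or p._backward is not None for p in parents):
        return Tensor(out_data, requires_grad=True, parents=parents,
                      backward=backward_builder())
    return Tensor(out_data)


# ----------------------------------------------------------------------
# element-wise ops
# ----------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def build():
        def backward(g):
            return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)
        return backward

    return make_op(out, (a, b), build)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data - b.data

    def build():
        def backward(g):
            return _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)
        return backward

    return make_op(out, (a, b), build)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def build():
        ad, bd = a.data, b.data

        def backward(g):
            return _unbroadcast(g * bd, ad.shape), _unbroadcast(g * ad, bd.shape)
        return backward

    return make_op(out, (a, b), build)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data

    def build():
        ad, bd = a.data, b.data

        def backward(g):
            return (_unbroadcast(g / bd, ad.shape),
                    _unbroadcast(-g * ad / (bd * bd), bd.shape))
        return backward

    return make_op(out, (a, b), build)


def _unbroadcast(g, shape):
    if g.shape == shape:
        return g
    # sum over broadcast axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def relu(x):
    x = as_tensor(x)
    out = np.maximum(x.data, 0)

    def build():
        mask = x.data > 0

        def backward(g):
            return (g * mask,)
        return backward

    return make_op(out, (x,), build)


def sigmoid(x):
    x = as_tensor(x)
    out = _sigmoid(x.data)

    def build():
        od = out

        def backward(g):
            return (g * od * (1.0 - od),)
        return backward

    return make_op(out, (x,), build)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def minimum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = np.minimum(a.data, b.data)

    def build():
        mask = a.data <= b.data

        def backward(g):
            return g * mask, g * ~mask
        return backward

    return make_op(out, (a, b), build)


def maximum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = np.maximum(a.data, b.data)

    def build():
        mask = a.data >= b.data

        def backward(g):
            return g * mask, g * ~mask
        return backward

    return make_op(out, (a, b), build)


def tsum(x):
    """Sum of all elements, as a 0-d tensor."""
    x = as_tensor(x)
    out = x.data.sum()

    def build():
        shape = x.data.shape
        dtype = x.data.dtype

        def backward(g):
            return (np.full(shape, g, dtype=dtype),)
        return backward

    return make_op(out, (x,), build)


def tmean(x):
    x = as_tensor(x)
    out = x.data.mean()

    def build():
        shape = x.data.shape
        dtype = x.data.dtype
        n = x.data.size

        def backward(g):
            return (np.full(shape, g / n, dtype=dtype),)
        return backward

    return make_op(out, (x,), build)
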