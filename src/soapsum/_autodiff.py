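"""Minimal reverse-mode automatic differentiation on numpy arrays.

The summarization model needs exact analytic gradients through LSTM
recurrences, two attention stages, a sigmoid copy gate and a scatter-add
over an extended vocabulary.  This module provides just the primitives
that computation uses: a :class:`Tensor` wrapping a float64 ndarray, a
tape built implicitly through parent links, and a topological-order
backward pass.  All arrays are float64; correctness (checked against
central finite differences in the test suite) is preferred over speed.

Broadcasting follows numpy; gradients of broadcast operands are
sum-reduced back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "concat",
    "tanh",
    "sigmoid",
    "log",
    "clip_min",
    "softmax",
    "minimum",
    "gather_rows",
    "take_per_row",
    "scatter_add",
    "narrow",
    "reshape",
    "sum_",
    "stack",
]


class Tensor:
    """A node in the computation graph.

    Leaf tensors created with ``requires_grad=True`` accumulate gradients
    in ``.grad`` after :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- shape helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    # -- autograd ------------------------------------------------------
    def backward(self, grad=None):
        """Run reverse-mode accumulation from this tensor.

        ``grad`` defaults to 1 and must match this tensor's shape.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order: graphs here can be thousands of
        # nodes deep (BPTT), recursion would overflow
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        grads: dict[int, np.ndarray] = {
            id(self): np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` so its shape matches a broadcast operand."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(out, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = a.data - b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)

    return _make(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return _make(out, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """``a @ b`` where ``a`` is (..., k) and ``b`` is a 2-D (k, m) matrix."""
    ad, bd = a.data, b.data
    lead = ad.shape[:-1]
    a2 = ad.reshape(-1, ad.shape[-1])
    out = (a2 @ bd).reshape(*lead, bd.shape[1])

    def backward(g):
        g2 = g.reshape(-1, bd.shape[1])
        da = (g2 @ bd.T).reshape(ad.shape)
        db = a2.T @ g2
        return da, db

    return _make(out, (a, b), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(out, tuple(tensors), backward)


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.data)

    def backward(g):
        return (g * (1.0 - out * out),)

    return _make(out, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return (g * out * (1.0 - out),)

    return _make(out, (a,), backward)


def log(a: Tensor) -> Tensor:
    out = np.log(a.data)

    def backward(g):
        return (g / a.data,)

    return _make(out, (a,), backward)


def clip_min(a: Tensor, lo: float) -> Tensor:
    """Elementwise max(a, lo); gradient passes only where a > lo."""
    out = np.maximum(a.data, lo)
    mask = (a.data > lo).astype(np.float64)

    def backward(g):
        return (g * mask,)

    return _make(out, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return _make(out, (a,), backward)


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise min; at ties the gradient goes to ``a`` (subgradient)."""
    out = np.minimum(a.data, b.data)
    a_wins = (a.data <= b.data).astype(np.float64)

    def backward(g):
        return (
            _unbroadcast(g * a_wins, a.shape),
            _unbroadcast(g * (1.0 - a_wins), b.shape),
        )

    return _make(out, (a, b), backward)


def gather_rows(table: Tensor, ids: np.ndarray) -> Tensor:
    """Embedding lookup: rows of a (V, d) table indexed by an int array."""
    ids = np.asarray(ids)
    out = table.data[ids]

    def backward(g):
        dt = np.zeros_like(table.data)
        np.add.at(dt, ids.reshape(-1), g.reshape(-1, table.data.shape[1]))
        return (dt,)

    return _make(out, (table,), backward)


def take_per_row(a: Tensor, idx: np.ndarray) -> Tensor:
    """For a (B, K) tensor return (B,) values a[b, idx[b]]."""
    idx = np.asarray(idx)
    rows = np.arange(a.data.shape[0])
    out = a.data[rows, idx]

    def backward(g):
        da = np.zeros_like(a.data)
        da[rows, idx] = g
        return (da,)

    return _make(out, (a,), backward)


def scatter_add(src: Tensor, idx: np.ndarray, size: int) -> Tensor:
    """Row-wise scatter: out[b, idx[b, j]] += src[b, j], out is (B, size)."""
    idx = np.asarray(idx)
    B = src.data.shape[0]
    out = np.zeros((B, size), dtype=np.float64)
    rows = np.repeat(np.arange(B), idx.shape[1])
    np.add.at(out, (rows, idx.reshape(-1)), src.data.reshape(-1))

    def backward(g):
        return (g[np.arange(B)[:, None], idx],)

    return _make(out, (src,), backward)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice of ``length`` elements along ``axis``."""
    index = [slice(None)] * a.ndim
    index[axis] = slice(start, start + length)
    index = tuple(index)
    out = a.data[index]

    def backward(g):
        da = np.zeros_like(a.data)
        da[index] = g
        return (da,)

    return _make(out, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    out = a.data.reshape(shape)

    def backward(g):
        return (g.reshape(a.data.shape),)

    return _make(out, (a,), backward)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return _make(out, (a,), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    out = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return _make(out, tuple(tensors), backward)
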