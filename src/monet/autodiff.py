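"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model layers in :mod:`monet.gnn_core` are expressed as compositions of the
primitives below; :mod:`monet.training` differentiates the masked loss through
the whole graph with :meth:`Tensor.backward`. The op set is deliberately small:
dense/sparse matrix products, elementwise arithmetic with broadcasting, the
activations the model uses, and gather/scatter primitives that make per-edge
attention (softmax over each node's neighbourhood) expressible without
materialising an N x N attention matrix.

Gradients are accumulated in float64. Every primitive is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import sparse as sp

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "neg", "matmul", "spmm",
    "relu", "elu", "leaky_relu", "sigmoid", "exp", "log", "softplus",
    "concat", "gather_rows", "scatter_add_rows", "segment_softmax",
    "sum_", "mean_", "as_tensor",
]


class Tensor:
    """An array node in the computation graph.

    Parameters with ``requires_grad=True`` collect gradients in ``.grad``
    after :meth:`backward`. Constants participate in the forward pass only.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; ``grad`` defaults to 1 for scalars."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over broadcast dimensions back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data - b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)))


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _make(-a.data, (a,), lambda g: (-g,))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.data.shape),
                            _unbroadcast(g * a.data, b.data.shape)))


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data / b.data, (a, b),
                 lambda g: (_unbroadcast(g / b.data, a.data.shape),
                            _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data @ b.data, (a, b),
                 lambda g: (g @ b.data.T, a.data.T @ g))


def spmm(a_sparse: sp.spmatrix, b) -> Tensor:
    """Sparse-constant @ dense product; gradient flows to the dense operand."""
    b = as_tensor(b)
    mat = sp.csr_matrix(a_sparse)
    return _make(mat @ b.data, (b,), lambda g: (mat.T @ g,))


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0.0)
    return _make(out, (a,), lambda g: (g * (a.data > 0), ))


def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    out = np.where(a.data > 0, a.data, negative_slope * a.data)
    return _make(out, (a,),
                 lambda g: (g * np.where(a.data > 0, 1.0, negative_slope),))


def elu(a, alpha: float = 1.0) -> Tensor:
    a = as_tensor(a)
    neg_part = alpha * np.expm1(np.minimum(a.data, 0.0))
    out = np.where(a.data > 0, a.data, neg_part)
    return _make(out, (a,),
                 lambda g: (g * np.where(a.data > 0, 1.0, neg_part + alpha),))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
    return _make(out, (a,), lambda g: (g * out * (1.0 - out),))


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return _make(out, (a,), lambda g: (g * out,))


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), lambda g: (g / a.data,))


def softplus(a) -> Tensor:
    """log(1 + exp(x)), overflow-safe; gradient is sigmoid(x)."""
    a = as_tensor(a)
    out = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))
    sig = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
    return _make(out, (a,), lambda g: (g * sig,))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def gather_rows(a, index: np.ndarray) -> Tensor:
    """Select rows ``a[index]``; backward scatter-adds into the source rows."""
    a = as_tensor(a)
    index = np.asarray(index, dtype=np.intp)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, index, g)
        return (out,)

    return _make(a.data[index], (a,), backward)


def scatter_add_rows(a, index: np.ndarray, n_rows: int) -> Tensor:
    """``out[index[k]] += a[k]``; the adjoint of :func:`gather_rows`."""
    a = as_tensor(a)
    index = np.asarray(index, dtype=np.intp)
    out = np.zeros((n_rows,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(out, index, a.data)
    return _make(out, (a,), lambda g: (g[index],))


def segment_softmax(logits, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of ``logits`` (shape (E, 1)) within groups given by ``segment_ids``.

    Used for attention coefficients: each segment is one node's neighbourhood.
    The max-shift for numerical stability is treated as a constant, which
    leaves the gradient unchanged (softmax is shift-invariant).
    """
    logits = as_tensor(logits)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    seg_max = np.full((n_segments, 1), -np.inf)
    np.maximum.at(seg_max, segment_ids, logits.data)
    shifted = sub(logits, Tensor(seg_max[segment_ids]))
    e = exp(shifted)
    denom = scatter_add_rows(e, segment_ids, n_segments)
    return div(e, gather_rows(denom, segment_ids))


def sum_(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.array(a.data.sum()), (a,),
                 lambda g: (np.broadcast_to(g, a.data.shape).copy(),))


def mean_(a) -> Tensor:
    a = as_tensor(a)
    n = a.data.size
    return _make(np.array(a.data.mean()), (a,),
                 lambda g: (np.broadcast_to(g / n, a.data.shape).copy(),))
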