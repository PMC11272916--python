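"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small convolutional encoder and transformer
decoder: broadcasting elementwise arithmetic, matmul, reshape/transpose,
reductions, fused softmax / log-softmax / cross-entropy, embedding lookup
and im2col convolution. Float32 throughout.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reversing numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return self._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._node(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return self._node(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._node(self.data @ other.data, (self, other), bwd)

    def __pow__(self, exponent: float):
        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return self._node(self.data ** exponent, (self,), bwd)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._node(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inverse = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inverse))

        return self._node(self.data.transpose(axes), (self,), bwd)

    # -- reductions & nonlinearities ----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._node(self.data * mask, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._node(out_data, (self,), bwd)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return self._node(out_data, (self,), bwd)

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        logsum = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - logsum
        soft = np.exp(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return self._node(out_data, (self,), bwd)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient."""
    ids = np.asarray(ids)

    def bwd(g):
        if table.requires_grad:
            grad = np.zeros_like(table.data)
            np.add.at(grad, ids.ravel(),
                      g.reshape(-1, table.data.shape[-1]))
            table._accum(grad)

    return Tensor._node(table.data[ids], (table,), bwd)


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  mask: np.ndarray) -> Tensor:
    """Mean token-level cross entropy over positions where ``mask`` is set.

    ``logits``: (..., V); ``targets``/``mask``: matching leading shape.
    """
    logp = logits.log_softmax(axis=-1)
    flat = logp.reshape(-1, logits.shape[-1])
    t = np.asarray(targets).ravel()
    m = np.asarray(mask, dtype=np.float32).ravel()
    picked = embedding_like_pick(flat, t)
    return -(picked * Tensor(m)).sum() * (1.0 / max(m.sum(), 1.0))


def embedding_like_pick(mat: Tensor, idx: np.ndarray) -> Tensor:
    """Select one column per row: ``mat[arange(n), idx]``."""
    n = mat.data.shape[0]
    rows = np.arange(n)

    def bwd(g):
        if mat.requires_grad:
            grad = np.zeros_like(mat.data)
            grad[rows, idx] = g
            mat._accum(grad)

    return Tensor._node(mat.data[rows, idx], (mat,), bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bwd)
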