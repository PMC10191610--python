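"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The equivariant network needs gradients through a modest set of operations
(broadcasted arithmetic, matrix products against weight matrices, gathers
and segment-sums over graph edges, exp/sqrt, reductions, concatenation).
This module provides exactly that set as a tape-based autograd: ``Tensor``
wraps an ndarray, records its parents, and ``backward()`` accumulates
gradients in reverse topological order.  Gradient correctness is verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "constant", "gather", "segment_sum", "concat"]

# Scatter-add as a sparse matmul (much faster than np.add.at).  The CSR
# operators are memoized per index array; the cache holds a reference to the
# index array so the id key stays valid.
_SCATTER_CACHE: dict[tuple[int, int, int], tuple[np.ndarray, sp.csr_matrix]] = {}


def _scatter_op(idx: np.ndarray, num: int) -> sp.csr_matrix:
    key = (id(idx), idx.shape[0], num)
    hit = _SCATTER_CACHE.get(key)
    if hit is None or hit[0] is not idx:
        if len(_SCATTER_CACHE) > 256:
            _SCATTER_CACHE.clear()
        mat = sp.csr_matrix(
            (np.ones(idx.shape[0]), (idx, np.arange(idx.shape[0]))),
            shape=(num, idx.shape[0]),
        )
        _SCATTER_CACHE[key] = (idx, mat)
        return mat
    return hit[1]


def _scatter_add(x: np.ndarray, idx: np.ndarray, num: int) -> np.ndarray:
    flat = x.reshape(x.shape[0], -1)
    out = _scatter_op(idx, num) @ flat
    return out.reshape((num,) + x.shape[1:])


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------------
    def backward(self, seed: np.ndarray | None = None) -> None:
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

        self.grad = np.ones_like(self.data) if seed is None else np.asarray(seed)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # first contribution is kept by reference; later ones allocate
        self.grad = grad if self.grad is None else self.grad + grad

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = back
        return out

    def __matmul__(self, other):
        """ND tensor @ 2D weight matrix (last axis contracted)."""
        other = _as_tensor(other)
        assert other.data.ndim == 2
        out = Tensor(self.data @ other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                x2 = self.data.reshape(-1, self.data.shape[-1])
                g2 = g.reshape(-1, g.shape[-1])
                other._accum(x2.T @ g2)

        out._backward = back
        return out

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * val)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * 0.5 / np.maximum(val, 1e-300)
        )
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (1.0 - val**2)
        )
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    # -- reductions / shape -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.shape)
        )
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """Wrap an array as a non-differentiable tensor."""
    return Tensor(np.asarray(x, dtype=np.float64))


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row selection ``x[idx]`` with scatter-add gradient."""
    out = Tensor(x.data[idx], parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accum(_scatter_add(g, idx, x.data.shape[0]))

    out._backward = back
    return out


def segment_sum(x: Tensor, idx: np.ndarray, num: int) -> Tensor:
    """out[i] = Σ_{e : idx[e]=i} x[e] along the first axis."""
    out = Tensor(_scatter_add(x.data, idx, num), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g[idx])
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = back
    return out
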