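"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the GNN harness needs: dense and sparse
matrix products, row gather/scatter (message passing), elementwise
nonlinearities, reductions, and broadcasting-aware arithmetic. Gradients are
accumulated by topological-order backpropagation from a scalar loss.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -------------------------------------------------------------- plumbing

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
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
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ------------------------------------------------------------ arithmetic

    def __add__(self, other):
        other = self._lift(other)
        def bwd(g):
            self._accum(g)
            other._accum(g)
        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)
        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)
        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1))
        return self._make(self.data**exponent, (self,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)
        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), bwd)

    # ------------------------------------------------------------ reductions

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # --------------------------------------------------------- nonlinearities

    def exp(self):
        out_data = np.exp(self.data)
        def bwd(g):
            self._accum(g * out_data)
        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))
        return self._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0
        def bwd(g):
            self._accum(g * mask)
        return self._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        mult = np.where(self.data > 0, 1.0, slope)
        def bwd(g):
            self._accum(g * mult)
        return self._make(self.data * mult, (self,), bwd)

    def elu(self, alpha: float = 1.0):
        neg = self.data <= 0
        expm1 = np.expm1(np.minimum(self.data, 0.0))
        out_data = np.where(neg, alpha * expm1, self.data)
        def bwd(g):
            self._accum(g * np.where(neg, alpha * (expm1 + 1.0), 1.0))
        return self._make(out_data, (self,), bwd)

    def softplus(self):
        # log(1 + e^x), computed stably
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        def bwd(g):
            self._accum(g * sig)
        return self._make(out_data, (self,), bwd)

    def sqrt(self):
        return self**0.5

    # ------------------------------------------------------- structured ops

    def gather(self, index: np.ndarray):
        """Select rows: ``out[i] = self[index[i]]``."""
        index = np.asarray(index, dtype=np.int64)
        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, index, g)
                self._accum(acc)
        return self._make(self.data[index], (self,), bwd)

    def scatter_add(self, index: np.ndarray, n_rows: int):
        """Segment sum: ``out[j] = sum_{i: index[i]=j} self[i]``."""
        index = np.asarray(index, dtype=np.int64)
        out_data = np.zeros((n_rows,) + self.data.shape[1:], dtype=np.float64)
        np.add.at(out_data, index, self.data)
        def bwd(g):
            self._accum(g[index])
        return self._make(out_data, (self,), bwd)

    def spmm(self, matrix: sp.spmatrix):
        """Constant sparse matrix product ``matrix @ self``."""
        mT = matrix.T.tocsr()
        def bwd(g):
            self._accum(mT @ g)
        return self._make(matrix @ self.data, (self,), bwd)

    def reshape(self, *shape):
        old = self.data.shape
        def bwd(g):
            self._accum(g.reshape(old))
        return self._make(self.data.reshape(*shape), (self,), bwd)


def segment_softmax(scores: Tensor, index: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of ``scores`` within segments defined by ``index``.

    The per-segment max is treated as a constant shift (it cancels in the
    gradient), matching the usual numerically stable formulation.
    """
    index = np.asarray(index, dtype=np.int64)
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, index, scores.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    shifted = scores - Tensor(seg_max[index])
    expd = shifted.exp()
    denom = expd.scatter_add(index, n_segments)
    return expd / denom.gather(index)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
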