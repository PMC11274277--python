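"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the GCN-LSTM needs: dense and
(constant-)sparse matrix products, broadcast addition, elementwise
multiplication, the relu/sigmoid/tanh nonlinearities, slicing, row
gathering, and a fused softmax cross-entropy. Gradients are accumulated
by topological sort over the recorded tape. Every op is gradient-checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "spmm", "cross_entropy", "Adam"]


class Tensor:
    """A numpy array plus a gradient and the closure that back-propagates it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Back-propagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- ops ---------------------------------------------------------------

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
        """Sum gradient over broadcast axes back to ``shape``."""
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, s in enumerate(shape):
            if s == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g

    def __add__(self, other: "Tensor | np.ndarray | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __mul__(self, other: "Tensor | np.ndarray | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor(s, parents=(self,), backward=bwd)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t * t))

        return Tensor(t, parents=(self,), backward=bwd)

    def sum(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, float(g)))

        return Tensor(self.data.sum(), parents=(self,), backward=bwd)


def spmm(a: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse (constant) @ dense (differentiable) matrix product."""
    out_data = a @ x.data

    def bwd(g):
        if x.requires_grad:
            x._accumulate(a.T @ g)

    return Tensor(out_data, parents=(x,), backward=bwd)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; backward is (softmax - onehot) / n."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))

    def bwd(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(float(g) * grad / n)

    return Tensor(loss, parents=(logits,), backward=bwd)


class Adam:
    """Adam with decoupled L2 weight decay added to the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1 ** self.t)
            vh = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
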