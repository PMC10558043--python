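"""Minimal reverse-mode automatic differentiation for the models in this package.

The cluster and interaction networks are small, full-batch, CPU-bound models
(a handful of dense layers, graph-convolution propagations through a fixed
normalized adjacency, Student's-t soft assignments, KL / focal losses).  This
module provides exactly the operator set those models need: a ``Tensor`` that
records its parents and a backward closure, dense and sparse matrix products,
elementwise nonlinearities, reductions, a numerically stable row softmax, a
``Dense`` layer and an Adam optimizer.  Gradients are verified against central
finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "Dense",
    "Adam",
    "add",
    "sub",
    "mul",
    "div",
    "matmul",
    "spmm",
    "relu",
    "sigmoid",
    "log",
    "exp",
    "power",
    "clip",
    "transpose",
    "reshape",
    "repeat0",
    "tsum",
    "tmean",
    "softmax_rows",
    "as_tensor",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph: value, gradient, and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Reverse-mode sweep seeding d(self)/d(self) = 1 (scalar outputs)."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad += pgrad

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        backward=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data - b.data,
        parents=(a, b),
        backward=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        backward=lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data / b.data,
        parents=(a, b),
        backward=lambda g: (
            _unbroadcast(g / b.data, a.shape),
            _unbroadcast(-g * a.data / (b.data**2), b.shape),
        ),
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        backward=lambda g: (g @ b.data.T, a.data.T @ g),
    )


def spmm(a_sparse: sp.spmatrix, b: Tensor) -> Tensor:
    """Constant sparse matrix times dense tensor (graph propagation)."""
    b = as_tensor(b)
    a_csr = sp.csr_matrix(a_sparse)
    at = a_csr.T.tocsr()
    return Tensor(a_csr @ b.data, parents=(b,), backward=lambda g: (at @ g,))


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, parents=(a,), backward=lambda g: (g * mask,))


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = 0.5 * (1.0 + np.tanh(0.5 * a.data))  # stable logistic
    return Tensor(out, parents=(a,), backward=lambda g: (g * out * (1.0 - out),))


def log(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return Tensor(np.log(a.data), parents=(a,), backward=lambda g: (g / a.data,))


def exp(a: Tensor) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g * out,))


def power(a: Tensor, p: float) -> Tensor:
    a = as_tensor(a)
    return Tensor(
        a.data**p,
        parents=(a,),
        backward=lambda g: (g * p * a.data ** (p - 1.0),),
    )


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through gradient inside the interval, zero outside."""
    a = as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)
    return Tensor(np.clip(a.data, lo, hi), parents=(a,), backward=lambda g: (g * mask,))


def transpose(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return Tensor(a.data.T, parents=(a,), backward=lambda g: (g.T,))


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    return Tensor(a.data.reshape(shape), parents=(a,),
                  backward=lambda g: (g.reshape(a.shape),))


def repeat0(a: Tensor, reps: int) -> Tensor:
    """Stack ``reps`` copies of a 2-D tensor along axis 0."""
    a = as_tensor(a)
    return Tensor(
        np.tile(a.data, (reps, 1)),
        parents=(a,),
        backward=lambda g: (g.reshape(reps, *a.shape).sum(axis=0),),
    )


def tsum(a: Tensor, axis: int | None = None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)

    def back(g: np.ndarray):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,), backward=back)


def tmean(a: Tensor, axis: int | None = None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.shape[axis]

    def back(g: np.ndarray):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy() / n,)

    return Tensor(a.data.mean(axis=axis, keepdims=keepdims), parents=(a,), backward=back)


def softmax_rows(a: Tensor) -> Tensor:
    """Row-wise softmax with the usual max-shift stabilization."""
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=1, keepdims=True)

    def back(g: np.ndarray):
        dot = (g * out).sum(axis=1, keepdims=True)
        return (out * (g - dot),)

    return Tensor(out, parents=(a,), backward=back)


class Dense:
    """Fully connected layer ``x @ W + b`` with Glorot-uniform weights."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros((1, n_out)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.W), self.b)

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data  # decoupled L2
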