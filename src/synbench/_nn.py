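"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Internal engine powering the learnable pieces of the framework: the MLP
decoder, the molecular-graph GCN encoder, the SMILES transformer encoder
and the autoencoder preprocessor.  The surface is deliberately tiny — only
the operations those models need — and every op is deterministic.

Gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "relu",
    "softmax",
    "layer_norm",
    "Linear",
    "Embedding",
    "MLP",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
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
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents: tuple = (), backward: Callable | None = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # ---- graph plumbing -------------------------------------------------
    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward()

    # ---- ops ------------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def back():
            if self.requires_grad:
                self.grad += _unbroadcast(out.grad, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(out.grad, other.shape)

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def back():
            if self.requires_grad:
                self.grad += -out.grad

        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def back():
            if self.requires_grad:
                self.grad += _unbroadcast(out.grad * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(out.grad * self.data, other.shape)

        out._backward = back
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def back():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other.grad += _unbroadcast(g, other.shape)

        out._backward = back
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def back():
            if self.requires_grad:
                self.grad += out.grad.reshape(self.shape)

        out._backward = back
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), (self,))

        def back():
            if self.requires_grad:
                self.grad += out.grad.transpose(inv)

        out._backward = back
        return out

    def take_rows(self, idx: np.ndarray):
        """Gather rows along axis 0 (embedding lookup)."""
        idx = np.asarray(idx, dtype=np.int64)
        out = Tensor(self.data[idx], (self,))

        def back():
            if self.requires_grad:
                np.add.at(self.grad, idx, out.grad)

        out._backward = back
        return out

    def slice_axis1(self, index: int):
        """x[:, index, :] keeping the leading axis."""
        out = Tensor(self.data[:, index], (self,))

        def back():
            if self.requires_grad:
                self.grad[:, index] += out.grad

        out._backward = back
        return out

    def max_axis0(self):
        """Coordinatewise max over axis 0 (global max pooling over nodes)."""
        arg = np.argmax(self.data, axis=0)
        out = Tensor(self.data[arg, np.arange(self.data.shape[1])], (self,))

        def back():
            if self.requires_grad:
                np.add.at(self.grad, (arg, np.arange(self.data.shape[1])), out.grad)

        out._backward = back
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))

        def back():
            if self.requires_grad:
                self.grad += out.grad

        out._backward = back
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), (self,))

        def back():
            if self.requires_grad:
                self.grad += out.grad / n

        out._backward = back
        return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))

    def back():
        if x.requires_grad:
            x.grad += out.grad * (x.data > 0)

    out._backward = back
    return out


def concat(parts: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def back():
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                p.grad += out.grad[tuple(sl)]

    out._backward = back
    return out


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    m = x.data.max(axis=-1, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s, (x,))

    def back():
        if x.requires_grad:
            g = out.grad
            x.grad += s * (g - (g * s).sum(axis=-1, keepdims=True))

    out._backward = back
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable affine."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, (x, gamma, beta))
    d = x.data.shape[-1]

    def back():
        g = out.grad
        if gamma.requires_grad:
            gamma.grad += _unbroadcast(g * xhat, gamma.shape)
        if beta.requires_grad:
            beta.grad += _unbroadcast(g, beta.shape)
        if x.requires_grad:
            gx = g * gamma.data
            x.grad += inv * (gx - gx.mean(axis=-1, keepdims=True)
                             - xhat * (gx * xhat).mean(axis=-1, keepdims=True))

    out._backward = back
    return out


# ---- layers -------------------------------------------------------------


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class Embedding:
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, 0.02, size=(n_rows, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.W.take_rows(idx)

    def parameters(self) -> list[Tensor]:
        return [self.W]


class MLP:
    """ReLU MLP with optional inverted dropout on hidden activations."""

    def __init__(self, n_in: int, hidden: Sequence[int], n_out: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        self.layers: list[Linear] = []
        last = n_in
        for h in hidden:
            self.layers.append(Linear(last, h, rng))
            last = h
        self.out = Linear(last, n_out, rng)
        self.dropout = float(dropout)
        self._rng = rng

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        for lyr in self.layers:
            x = relu(lyr(x))
            if train and self.dropout > 0.0:
                mask = (self._rng.random(x.shape) >= self.dropout) / (1.0 - self.dropout)
                x = x * Tensor(mask)
        return self.out(x)

    def parameters(self) -> list[Tensor]:
        ps = [p for lyr in self.layers for p in lyr.parameters()]
        return ps + self.out.parameters()


class Adam:
    """Adam optimizer (Kingma & Ba) over a fixed parameter list."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def get_state(params: Sequence[Tensor]) -> list[np.ndarray]:
    return [p.data.copy() for p in params]


def set_state(params: Sequence[Tensor], state: Sequence[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.data = s.copy()
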