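"""Minimal reverse-mode autodiff and neural-network layer over NumPy.

Provides exactly the primitives the sequence encoders need: broadcast-aware
arithmetic, batched matmul, fused softmax / layer-norm / cross-entropy,
embedding lookup with scatter-add gradients, dropout, and an AdamW optimizer.
All computation is float32. Gradients are accumulated by topological sweep
over a dynamically recorded tape, in the style of micrograd but on ndarrays.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing -------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
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

    # -- arithmetic -----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = _node(self.data + other.data, (self, other))
        if out._parents:
            def bwd(g):
                if self.requires_grad or self._parents:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out._parents:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = _node(self.data * other.data, (self, other))
        if out._parents:
            def bwd(g):
                if self.requires_grad or self._parents:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = _node(self.data @ other.data, (self, other))
        if out._parents:
            def bwd(g):
                if self.requires_grad or self._parents:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(ga, self.data.shape))
                if other.requires_grad or other._parents:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accum(_unbroadcast(gb, other.data.shape))
            out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out._parents:
            def bwd(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bwd
        return out

    # -- shape ops ------------------------------------------------------

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        if out._parents:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = _node(self.data.transpose(*axes), (self,))
        if out._parents:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bwd(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), (self,))
        if out._parents:
            out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _node(y, (self,))
        if out._parents:
            out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(y, (self,))
        if out._parents:
            out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = _node(x * cdf, (self,))
        if out._parents:
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            out._backward = lambda g: self._accum(g * (cdf + x * pdf))
        return out


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
    return out


# -- fused ops -----------------------------------------------------------


def softmax(x: Tensor, bias: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; `bias` is a constant additive mask."""
    z = x.data if bias is None else x.data + bias
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = _node(s, (x,))
    if out._parents:
        def bwd(g):
            dot = (g * s).sum(axis=-1, keepdims=True)
            x._accum(s * (g - dot))
        out._backward = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv
    out = _node(y * gamma.data + beta.data, (x, gamma, beta))
    if out._parents:
        def bwd(g):
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * y, gamma.data.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.data.shape))
            gy = g * gamma.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * y).mean(axis=-1, keepdims=True)
            x._accum(inv * (gy - m1 - y * m2))
        out._backward = bwd
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    out = _node(weight.data[ids], (weight,))
    if out._parents:
        def bwd(g):
            gw = np.zeros_like(weight.data)
            np.add.at(gw, ids.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
            weight._accum(gw)
        out._backward = bwd
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy over rows; `logits` is (N, V), `targets` (N,) int."""
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    nll = lse - z[np.arange(n), targets]
    out = _node(np.asarray(nll.mean()), (logits,))
    if out._parents:
        def bwd(g):
            p = np.exp(z - lse[:, None])
            p[np.arange(n), targets] -= 1.0
            logits._accum(g * p / n)
        out._backward = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    if not train or rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate).astype(DTYPE) / (1.0 - rate)
    return x * Tensor(keep)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _node(np.concatenate(datas, axis=axis), (*tensors,))
    if out._parents:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]
        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accum(piece)
        out._backward = bwd
    return out


# -- parameters and optimizer --------------------------------------------


class ParamStore(dict):
    """Named parameter registry; values are trainable Tensors."""

    def add(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self[name] = t
        return t

    def n_params(self) -> int:
        return int(sum(t.data.size for t in self.values()))

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.items():
            v.data[...] = state[k]

    def zero_grad(self) -> None:
        for t in self.values():
            t.grad = None


def normal_init(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return (rng.standard_normal(shape) * std).astype(DTYPE)


class AdamW:
    """AdamW with decoupled weight decay; lr is set per-step by the caller."""

    def __init__(self, params: ParamStore, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.wd * p.data)
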