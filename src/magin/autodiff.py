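"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operation that produced
it; :meth:`Tensor.backward` runs the reverse sweep in topological order.
The operation set is exactly what the graph encoders and the fusion head
need: matmul (dense and sparse-constant), broadcasting add/mul, ReLU,
sigmoid, row softmax (with optional additive mask), LayerNorm, dropout,
column concat/slice, row gather, per-node neighbor max, means, and a
numerically stable binary cross-entropy on logits.  An Adam optimizer
closes the loop.

Gradients accumulate in float64; every backward rule is exercised against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(self, data, parents=(), backward=None, requires_grad=False,
                 name=""):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, name={self.name!r})"


def parameter(data, rng=None, name="") -> Tensor:
    return Tensor(np.array(data, dtype=float), requires_grad=True, name=name)


def constant(data) -> Tensor:
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum *g* down to *shape* (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# -- arithmetic ---------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))
    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))
    out._backward = bw
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, (a,))
    out._backward = lambda g: a.requires_grad and a.accumulate(g * s)
    return out


def add_n(tensors) -> Tensor:
    tensors = list(tensors)
    out = tensors[0]
    for t in tensors[1:]:
        out = add(out, t)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)
    out._backward = bw
    return out


def spmm(S, x: Tensor) -> Tensor:
    """Sparse-constant @ dense: S is a fixed scipy sparse matrix."""
    out = Tensor(S @ x.data, (x,))
    ST = S.T.tocsr() if sp.issparse(S) else S.T

    def bw(g):
        if x.requires_grad:
            x.accumulate(ST @ g)
    out._backward = bw
    return out


# -- nonlinearities -----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))
    out._backward = lambda g: x.requires_grad and x.accumulate(g * (x.data > 0))
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out = Tensor(np.where(x.data > 0, x.data, slope * x.data), (x,))
    out._backward = lambda g: x.requires_grad and x.accumulate(
        g * np.where(x.data > 0, 1.0, slope))
    return out


def sigmoid(x: Tensor) -> Tensor:
    # stable piecewise form
    y = np.where(x.data >= 0,
                 1.0 / (1.0 + np.exp(-np.clip(x.data, 0, None))),
                 np.exp(np.clip(x.data, None, 0))
                 / (1.0 + np.exp(np.clip(x.data, None, 0))))
    out = Tensor(y, (x,))
    out._backward = lambda g: x.requires_grad and x.accumulate(g * y * (1 - y))
    return out


def softmax_rows(x: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Row-wise softmax; *mask* (additive, e.g. -inf off-graph) is constant."""
    z = x.data if mask is None else x.data + mask
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, (x,))

    def bw(g):
        if x.requires_grad:
            x.accumulate(y * (g - (g * y).sum(axis=-1, keepdims=True)))
    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Per-row normalization over the feature axis with learnable affine."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, (x, gamma, beta))
    n = x.data.shape[-1]

    def bw(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gh = g * gamma.data
            gx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                        - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
            x.accumulate(gx)
    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout: active only in training mode."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    out = Tensor(x.data * keep, (x,))
    out._backward = lambda g: x.requires_grad and x.accumulate(g * keep)
    return out


# -- shaping ------------------------------------------------------------------

def concat_cols(tensors) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), tensors)
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

    def bw(g):
        for t, gi in zip(tensors, np.split(g, splits, axis=1)):
            if t.requires_grad:
                t.accumulate(gi)
    out._backward = bw
    return out


def slice_cols(x: Tensor, a: int, b: int) -> Tensor:
    out = Tensor(x.data[:, a:b], (x,))

    def bw(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, a:b] = g
            x.accumulate(full)
    out._backward = bw
    return out


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=int)
    out = Tensor(x.data[idx], (x,))

    def bw(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, idx, g)
            x.accumulate(full)
    out._backward = bw
    return out


def mean_rows(x: Tensor) -> Tensor:
    """Mean over rows -> 1 x d."""
    out = Tensor(x.data.mean(axis=0, keepdims=True), (x,))
    m = x.data.shape[0]
    out._backward = lambda g: x.requires_grad and x.accumulate(
        np.repeat(g, m, axis=0) / m)
    return out


def broadcast_rows(x: Tensor, m: int) -> Tensor:
    """Tile a 1 x d row to m identical rows."""
    out = Tensor(np.repeat(x.data, m, axis=0), (x,))
    out._backward = lambda g: x.requires_grad and x.accumulate(
        g.sum(axis=0, keepdims=True))
    return out


def neighbor_max(x: Tensor, neighbors) -> Tensor:
    """Row v of the output is the elementwise max over x[neighbors[v]].

    The max over an empty neighborhood is defined as the zero vector, so
    isolated nodes contribute nothing.  Gradients route to the argmax row
    per (node, feature); ties go to the first listed neighbor, matching
    ``np.argmax``.
    """
    m, d = x.data.shape
    out_data = np.zeros((m, d))
    arg = np.full((m, d), -1, dtype=int)
    for v, nb in enumerate(neighbors):
        if len(nb) == 0:
            continue
        sub = x.data[nb]
        k = np.argmax(sub, axis=0)
        out_data[v] = sub[k, np.arange(d)]
        arg[v] = np.asarray(nb)[k]
    out = Tensor(out_data, (x,))

    def bw(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            rows = arg.ravel()
            cols = np.tile(np.arange(d), m)
            ok = rows >= 0
            np.add.at(full, (rows[ok], cols[ok]), g.ravel()[ok])
            x.accumulate(full)
    out._backward = bw
    return out


def mean_neighbors(x: Tensor, neighbors) -> Tensor:
    """Row v = mean over x[neighbors[v]]; zero vector for isolated nodes."""
    m, d = x.data.shape
    rows, cols, vals = [], [], []
    for v, nb in enumerate(neighbors):
        for u in nb:
            rows.append(v)
            cols.append(int(u))
            vals.append(1.0 / len(nb))
    S = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    return spmm(S, x)


# -- losses -------------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, computed stably from logits."""
    z, y = logits.data, np.asarray(targets, dtype=float)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), (logits,))
    n = z.size

    def bw(g):
        if logits.requires_grad:
            s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, 0, None))),
                         np.exp(np.clip(z, None, 0))
                         / (1.0 + np.exp(np.clip(z, None, 0))))
            logits.accumulate(g * (s - y) / n)
    out._backward = bw
    return out


# -- layers -------------------------------------------------------------------

def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Linear:
    """Affine map y = x W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 name: str = "linear"):
        self.W = parameter(glorot(rng, d_in, d_out), name=f"{name}.W")
        self.b = parameter(np.zeros(d_out), name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.W), self.b)

    def parameters(self):
        return [self.W, self.b]


class LayerNormParams:
    def __init__(self, d: int, name: str = "ln"):
        self.gamma = parameter(np.ones(d), name=f"{name}.gamma")
        self.beta = parameter(np.zeros(d), name=f"{name}.beta")

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)

    def parameters(self):
        return [self.gamma, self.beta]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
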