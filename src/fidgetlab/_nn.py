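"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the graph pieces the convolutional and variational models
in this package need: broadcast arithmetic, matmul, valid-mode 1-D
convolution, max-pooling, ReLU, dropout, concatenation, reductions, and a
fused softmax cross-entropy. Gradients are accumulated over a
topologically-sorted tape; everything is deterministic given the RNGs
passed in. Checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, data, parents: Tuple["Tensor", ...] = (),
                 bwd: Optional[Callable] = None, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph traversal ---------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: List[Tensor] = []
        seen = set()

        def visit(node: "Tensor"):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n.parents:
                    stack.append((p, False))

        visit(self)
        for n in topo:
            n.grad = np.zeros_like(n.data)
        self.grad = np.ones_like(self.data)
        for n in reversed(topo):
            if n.bwd is not None:
                n.bwd(n.grad)

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _accum(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        t.grad += _unbroadcast(g, t.data.shape)


# ---------------------------------------------------------------------------
# Primitive ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out.bwd = lambda g: (_accum(a, g), _accum(b, g))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    out.bwd = lambda g: (_accum(a, g * b.data), _accum(b, g * a.data))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def bwd(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)
    out.bwd = bwd
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out.bwd = lambda g: _accum(a, g * mask)
    return out


def exp(a: Tensor) -> Tensor:
    val = np.exp(a.data)
    out = Tensor(val, (a,))
    out.bwd = lambda g: _accum(a, g * val)
    return out


def sqrt(a: Tensor) -> Tensor:
    val = np.sqrt(a.data)
    out = Tensor(val, (a,))
    out.bwd = lambda g: _accum(a, g * 0.5 / np.maximum(val, 1e-12))
    return out


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the range."""
    mask = (a.data > lo) & (a.data < hi)
    out = Tensor(np.clip(a.data, lo, hi), (a,))
    out.bwd = lambda g: _accum(a, g * mask)
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), (a,))
    out.bwd = lambda g: _accum(a, g.reshape(a.data.shape))
    return out


def concat(parts: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis),
                 tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for p, gp in zip(parts, np.split(g, splits, axis=axis)):
            _accum(p, gp)
    out.bwd = bwd
    return out


def tsum(a: Tensor, axis=None) -> Tensor:
    out = Tensor(a.data.sum(axis=axis), (a,))

    def bwd(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape))
        else:
            _accum(a, np.broadcast_to(np.expand_dims(g, axis), a.data.shape))
    out.bwd = bwd
    return out


def tmean(a: Tensor, axis=None) -> Tensor:
    count = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis), _as_tensor(1.0 / count))


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid-mode 1-D convolution: (B, T, C) * (K, C, F) + (F,) -> (B, T-K+1, F)."""
    B, T, C = x.data.shape
    K, _, F = w.data.shape
    cols = sliding_window_view(x.data, K, axis=1)       # (B, T', C, K)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))  # (B, T', K, C)
    Tn = T - K + 1
    flat = cols.reshape(B * Tn, K * C)
    wf = w.data.reshape(K * C, F)
    out = Tensor((flat @ wf).reshape(B, Tn, F) + b.data, (x, w, b))

    def bwd(g):
        gf = g.reshape(B * Tn, F)
        _accum(w, (flat.T @ gf).reshape(K, C, F))
        _accum(b, g.sum(axis=(0, 1)))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gcols = (gf @ wf.T).reshape(B, Tn, K, C)
            for k in range(K):
                gx[:, k:k + Tn, :] += gcols[:, :, k, :]
            _accum(x, gx)
    out.bwd = bwd
    return out


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    B, T, C = x.data.shape
    Tn = T // size
    xr = x.data[:, :Tn * size, :].reshape(B, Tn, size, C)
    idx = xr.argmax(axis=2)
    out = Tensor(np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :],
                 (x,))

    def bwd(g):
        gx = np.zeros((B, Tn, size, C))
        np.put_along_axis(gx, idx[:, :, None, :], g[:, :, None, :], axis=2)
        full = np.zeros_like(x.data)
        full[:, :Tn * size, :] = gx.reshape(B, Tn * size, C)
        _accum(x, full)
    out.bwd = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    if not train or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return mul(x, _as_tensor(mask))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy_soft(logits: Tensor,
                               target_probs: np.ndarray) -> Tensor:
    """Mean cross-entropy against a soft target distribution."""
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    eps = 1e-12
    loss = -(target_probs * np.log(probs + eps)).sum(axis=1).mean()
    out = Tensor(loss, (logits,))
    out.bwd = lambda g: _accum(logits, g * (probs - target_probs) / n)
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy (nats) between softmax(logits) and integer targets."""
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), targets] + eps).mean()
    out = Tensor(loss, (logits,))

    def bwd(g):
        grad = probs.copy()
        grad[np.arange(n), targets] -= 1.0
        _accum(logits, g * grad / n)
    out.bwd = bwd
    return out


# ---------------------------------------------------------------------------
# Parameters, layers, optimizer
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, shape, fan_in: int,
           fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Parameter(glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.w), self.b)

    @property
    def params(self) -> List[Parameter]:
        return [self.w, self.b]


class Conv1D:
    def __init__(self, kernel: int, c_in: int, c_out: int,
                 rng: np.random.Generator):
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.w = Parameter(glorot(rng, (kernel, c_in, c_out), fan_in, fan_out))
        self.b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)

    @property
    def params(self) -> List[Parameter]:
        return [self.w, self.b]


def l2_penalty(params: Sequence[Parameter], weight: float) -> Tensor:
    total = _as_tensor(0.0)
    for p in params:
        total = add(total, tsum(mul(p, p)))
    return mul(total, _as_tensor(weight))


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
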