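"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The pre-installed scientific stack ships no deep-learning framework, so the
recurrent model is built on this small, float64, CPU-only engine. It supports
exactly the operations the network needs (broadcast arithmetic, matmul with
batched left operands, tanh/sigmoid/exp, axis reductions, concat/stack/reshape
and basic indexing) plus an Adam optimizer.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape*, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing ----------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Accumulate gradients of this (typically scalar) tensor into its ancestors."""
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(_toposort(self)):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- operators ---------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_ensure(other), -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order


# -- primitive operations --------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = Tensor(a.data + b.data, _parents=(a, b))

    def backward(g):
        a._accum(g)
        b._accum(g)

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = Tensor(a.data * b.data, _parents=(a, b))

    def backward(g):
        a._accum(g * b.data)
        b._accum(g * a.data)

    out._backward = backward
    return out


def div(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = Tensor(a.data / b.data, _parents=(a, b))

    def backward(g):
        a._accum(g / b.data)
        b._accum(-g * a.data / (b.data * b.data))

    out._backward = backward
    return out


def matmul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def backward(g):
        a._accum(g @ np.swapaxes(b.data, -1, -2))
        b._accum(np.swapaxes(a.data, -1, -2) @ g)

    out._backward = backward
    return out


def tanh(a) -> Tensor:
    a = _ensure(a)
    t = np.tanh(a.data)
    out = Tensor(t, _parents=(a,))

    def backward(g):
        a._accum(g * (1.0 - t * t))

    out._backward = backward
    return out


def sigmoid(a) -> Tensor:
    a = _ensure(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, _parents=(a,))

    def backward(g):
        a._accum(g * s * (1.0 - s))

    out._backward = backward
    return out


def exp(a) -> Tensor:
    a = _ensure(a)
    e = np.exp(a.data)
    out = Tensor(e, _parents=(a,))

    def backward(g):
        a._accum(g * e)

    out._backward = backward
    return out


def tensor_sum(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape))

    out._backward = backward
    return out


def reshape(a, shape) -> Tensor:
    a = _ensure(a)
    out = Tensor(a.data.reshape(shape), _parents=(a,))

    def backward(g):
        a._accum(g.reshape(a.data.shape))

    out._backward = backward
    return out


def getitem(a, idx) -> Tensor:
    a = _ensure(a)
    out = Tensor(a.data[idx], _parents=(a,))

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] += g
        a._accum(full)

    out._backward = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0, *sizes])

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    out._backward = backward
    return out


def transpose(a, axes: tuple[int, ...]) -> Tensor:
    a = _ensure(a)
    out = Tensor(np.transpose(a.data, axes), _parents=(a,))
    inverse = np.argsort(axes)

    def backward(g):
        a._accum(np.transpose(g, inverse))

    out._backward = backward
    return out


def flip(a, axis: int = 0) -> Tensor:
    a = _ensure(a)
    out = Tensor(np.flip(a.data, axis=axis), _parents=(a,))

    def backward(g):
        a._accum(np.flip(g, axis=axis))

    out._backward = backward
    return out


def lstm(xs, Wx, Wh, b) -> Tensor:
    """One LSTM direction over a sequence, fused into a single graph node.

    Parameters
    ----------
    xs : Tensor, shape (T, B, n_in)
        Input sequence (step-major).
    Wx : Tensor, shape (n_in, 4u)
    Wh : Tensor, shape (u, 4u)
    b : Tensor, shape (1, 4u)
        Gate order along the last axis: input, forget, cell, output.

    Returns
    -------
    Tensor, shape (T, B, u) — hidden states at every step.

    The backward pass is hand-written truncated-free BPTT; correctness is
    pinned by the numeric gradient checks in the test suite.
    """
    xs, Wx, Wh, b = map(_ensure, (xs, Wx, Wh, b))
    T, B, _ = xs.data.shape
    u = Wh.data.shape[0]
    h = np.zeros((B, u))
    c = np.zeros((B, u))
    hs = np.empty((T, B, u))
    cache = []
    for t in range(T):
        z = xs.data[t] @ Wx.data + h @ Wh.data + b.data
        i = 1.0 / (1.0 + np.exp(-z[:, :u]))
        f = 1.0 / (1.0 + np.exp(-z[:, u : 2 * u]))
        g = np.tanh(z[:, 2 * u : 3 * u])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * u :]))
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        cache.append((h, c, i, f, g, o, tc))
        c = c_new
        h = o * tc
        hs[t] = h
    out = Tensor(hs, _parents=(xs, Wx, Wh, b))

    def backward(grad):
        dWx = np.zeros_like(Wx.data)
        dWh = np.zeros_like(Wh.data)
        db = np.zeros_like(b.data)
        dxs = np.zeros_like(xs.data) if xs.requires_grad else None
        dh = np.zeros((B, u))
        dc = np.zeros((B, u))
        dz = np.empty((B, 4 * u))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dh + grad[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz[:, :u] = di * i * (1.0 - i)
            dz[:, u : 2 * u] = df * f * (1.0 - f)
            dz[:, 2 * u : 3 * u] = dg * (1.0 - g * g)
            dz[:, 3 * u :] = do * o * (1.0 - o)
            dWx += xs.data[t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0, keepdims=True)
            if dxs is not None:
                dxs[t] = dz @ Wx.data.T
            dh = dz @ Wh.data.T
            dc = dc * f
        if dxs is not None:
            xs._accum(dxs)
        Wx._accum(dWx)
        Wh._accum(dWh)
        b._accum(db)

    out._backward = backward
    return out


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax composed from primitive ops."""
    a = _ensure(a)
    shifted = add(a, -a.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return div(e, tensor_sum(e, axis=axis, keepdims=True))


def square(a) -> Tensor:
    return mul(a, a)


# -- optimizer -------------------------------------------------------------


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
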