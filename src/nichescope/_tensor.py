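"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the neighborhood transformer:
broadcasting arithmetic, matmul, reductions, reshaping/gather, and the
special functions of the zero-inflated negative binomial likelihood
(log-gamma, logaddexp, softplus).  Gradients are float64 throughout.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy import special

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the block (evaluation mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    # defer mixed numpy/Tensor arithmetic to the reflected operators below
    __array_ufunc__ = None
    __array_priority__ = 1000.0

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    # -- plumbing --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free graph references
        for node in topo:
            node._parents = ()
            node._backward = None

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, pow_(other, -1.0)) if isinstance(other, Tensor) else mul(self, 1.0 / np.asarray(other))

    def __rtruediv__(self, other):
        return mul(pow_(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return pow_(self, p)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return sum_(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def swapaxes(self, a, b):
        return swapaxes(self, a, b)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unary(x, value, dvalue):
    x = as_tensor(x)
    data = value(x.data)

    def backward(grad):
        if x.requires_grad:
            x._accum(grad * dvalue(x.data, data))

    return _make(data, (x,), backward)


# -- primitive operations -------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(grad):
        if a.requires_grad:
            a._accum(_unbroadcast(grad, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(grad, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(grad):
        if a.requires_grad:
            a._accum(_unbroadcast(grad * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(grad * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def pow_(x, p: float):
    x = as_tensor(x)
    p = float(p)
    return _unary(x, lambda d: d ** p, lambda d, out: p * d ** (p - 1.0))


def exp(x):
    return _unary(x, np.exp, lambda d, out: out)


def log(x):
    return _unary(x, np.log, lambda d, out: 1.0 / d)


def tanh(x):
    return _unary(x, np.tanh, lambda d, out: 1.0 - out * out)


def erf(x):
    return _unary(x, special.erf, lambda d, out: (2.0 / np.sqrt(np.pi)) * np.exp(-d * d))


def sigmoid(x):
    return _unary(x, special.expit, lambda d, out: out * (1.0 - out))


def softplus(x):
    return _unary(x, lambda d: np.logaddexp(0.0, d), lambda d, out: special.expit(d))


def lgamma(x):
    return _unary(x, special.gammaln, lambda d, out: special.psi(d))


def gelu(x):
    """Exact GELU: x * Phi(x)."""
    x = as_tensor(x)
    return mul(mul(x, 0.5), add(1.0, erf(mul(x, 1.0 / np.sqrt(2.0)))))


def logaddexp(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = np.logaddexp(a.data, b.data)

    def backward(grad):
        if a.requires_grad:
            a._accum(_unbroadcast(grad * np.exp(a.data - data), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(grad * np.exp(b.data - data), b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(grad):
        if a.requires_grad:
            ga = grad @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ grad
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def sum_(x, axis=None, keepdims=False):
    x = as_tensor(x)
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        if x.requires_grad:
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            x._accum(np.broadcast_to(g, x.data.shape).copy())

    return _make(data, (x,), backward)


def reshape(x, shape):
    x = as_tensor(x)
    data = x.data.reshape(shape)

    def backward(grad):
        if x.requires_grad:
            x._accum(grad.reshape(x.data.shape))

    return _make(data, (x,), backward)


def swapaxes(x, a_ax, b_ax):
    x = as_tensor(x)
    data = np.swapaxes(x.data, a_ax, b_ax)

    def backward(grad):
        if x.requires_grad:
            x._accum(np.swapaxes(grad, a_ax, b_ax))

    return _make(data, (x,), backward)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(grad[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def take(x, idx):
    """Row gather / basic indexing with gradient scatter-add."""
    x = as_tensor(x)
    data = x.data[idx]

    def backward(grad):
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.add.at(g, idx, grad)
            x._accum(g)

    return _make(data, (x,), backward)


def softmax(x, axis=-1, mask: np.ndarray | None = None):
    """Numerically stable softmax; `mask` (bool, broadcastable) marks valid slots.

    Invalid slots receive exactly zero weight and contribute exactly zero to
    the normalizer, so padding never perturbs the result.
    """
    x = as_tensor(x)
    d = x.data
    if mask is not None:
        neg = np.where(mask, d, -np.inf)
        m = neg.max(axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.exp(neg - m)  # exp(-inf) == exactly 0.0 for masked slots
    else:
        m = d.max(axis=axis, keepdims=True)
        e = np.exp(d - m)
    s = e.sum(axis=axis, keepdims=True)
    out_data = e / s

    def backward(grad):
        if x.requires_grad:
            g = out_data * (grad - (grad * out_data).sum(axis=axis, keepdims=True))
            x._accum(g)

    return _make(out_data, (x,), backward)


def layer_norm(x, gamma, beta, eps: float = 1e-5, axis: int = -1):
    """Pre-norm building block: normalize over `axis`, then scale and shift."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.mean(axis=axis, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=axis, keepdims=True)
    inv = pow_(var + eps, -0.5)
    return xc * inv * gamma + beta
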