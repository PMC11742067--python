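"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a Transformer encoder: broadcasting add/mul,
batched matmul, reshape/swapaxes/concat, reductions, fused softmax /
log-softmax / layer-norm / GELU / sigmoid, elementwise log and power, and
embedding lookup.  Tensors are float32 by default; wrap code in
``use_dtype(np.float64)`` when an oracle check needs tight precision.
``no_grad()`` disables graph construction for evaluation passes.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Optional

import numpy as np

__all__ = ["Tensor", "no_grad", "concat", "embedding", "gather_last",
           "use_dtype", "DTYPE"]

_GRAD_ENABLED = True

#: float32 by default (the training loops are bandwidth-bound); switch to
#: float64 with use_dtype for high-precision checks.
DTYPE = np.float32


@contextlib.contextmanager
def use_dtype(dtype):
    """Temporarily change the dtype used for newly created tensors."""
    global DTYPE
    prev = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = prev


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=DTYPE), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype != DTYPE:
            data = data.astype(DTYPE)
        self.data = data
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may be a broadcast view or shared buffer
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
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

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        a, b = self, _as_tensor(other)
        out_req = a.requires_grad or b.requires_grad

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor(a.data + b.data, out_req, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, _as_tensor(other)
        out_req = a.requires_grad or b.requires_grad

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor(a.data * b.data, out_req, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        b = _as_tensor(other)
        return self * b.pow(-1.0)

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)
        out_req = a.requires_grad or b.requires_grad

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

        return Tensor(a.data @ b.data, out_req, (a, b), bw)

    def pow(self, exponent: float) -> "Tensor":
        a = self
        out = np.power(a.data, exponent)

        def bw(g):
            a._accum(g * exponent * np.power(a.data, exponent - 1.0))

        return Tensor(out, a.requires_grad, (a,), bw)

    def log(self) -> "Tensor":
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor(np.log(a.data), a.requires_grad, (a,), bw)

    # -- shape ------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        a = self
        orig = a.shape

        def bw(g):
            a._accum(g.reshape(orig))

        return Tensor(a.data.reshape(*shape), a.requires_grad, (a,), bw)

    def swapaxes(self, ax1: int, ax2: int) -> "Tensor":
        a = self

        def bw(g):
            a._accum(np.swapaxes(g, ax1, ax2))

        return Tensor(np.swapaxes(a.data, ax1, ax2), a.requires_grad, (a,), bw)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor(a.data.sum(axis=axis, keepdims=keepdims),
                      a.requires_grad, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- fused nonlinearities --------------------------------------------

    def gelu(self) -> "Tensor":
        """GELU via the tanh approximation
        0.5 x (1 + tanh(sqrt(2/pi) (x + 0.044715 x^3)))."""
        a = self
        x = a.data
        c = x.dtype.type(np.sqrt(2.0 / np.pi))
        inner = c * (x + x.dtype.type(0.044715) * x * x * x)
        th = np.tanh(inner)
        out = 0.5 * x * (1.0 + th)

        def bw(g):
            sech2 = 1.0 - th * th
            dinner = c * (1.0 + x.dtype.type(3 * 0.044715) * x * x)
            a._accum(g * (0.5 * (1.0 + th) + 0.5 * x * sech2 * dinner))

        return Tensor(out, a.requires_grad, (a,), bw)

    def softplus(self) -> "Tensor":
        """log(1 + exp(x)), overflow-safe; derivative sigmoid(x)."""
        a = self
        x = a.data
        out = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))

        def bw(g):
            a._accum(g / (1.0 + np.exp(-x)))

        return Tensor(out, a.requires_grad, (a,), bw)

    def sigmoid(self) -> "Tensor":
        a = self
        out = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * out * (1.0 - out))

        return Tensor(out, a.requires_grad, (a,), bw)

    def softmax(self) -> "Tensor":
        """Softmax over the last axis."""
        a = self
        z = a.data - a.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=-1, keepdims=True)

        def bw(g):
            a._accum(out * (g - (g * out).sum(axis=-1, keepdims=True)))

        return Tensor(out, a.requires_grad, (a,), bw)

    def log_softmax(self) -> "Tensor":
        """Log-softmax over the last axis (numerically stable)."""
        a = self
        z = a.data - a.data.max(axis=-1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        out = z - lse
        soft = np.exp(out)

        def bw(g):
            a._accum(g - soft * g.sum(axis=-1, keepdims=True))

        return Tensor(out, a.requires_grad, (a,), bw)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-6) -> "Tensor":
        """Layer normalisation over the last axis with learned gain/bias."""
        a = self
        x = a.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = gain.data * xhat + bias.data
        out_req = a.requires_grad or gain.requires_grad or bias.requires_grad

        def bw(g):
            D = x.shape[-1]
            if gain.requires_grad:
                gain._accum(_unbroadcast(g * xhat, gain.shape))
            if bias.requires_grad:
                bias._accum(_unbroadcast(g, bias.shape))
            if a.requires_grad:
                dxhat = g * gain.data
                term = (
                    dxhat
                    - dxhat.mean(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
                )
                a._accum(term * inv)

        return Tensor(out, out_req, (a, gain, bias), bw)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    out_req = any(t.requires_grad for t in tensors)

    def bw(g):
        splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, gt in zip(tensors, splits):
            if t.requires_grad:
                t._accum(gt)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  out_req, tuple(tensors), bw)


def gather_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """Pick ``x[..., idx]`` along the last axis; ``idx.shape == x.shape[:-1]``."""
    idx = np.asarray(idx)
    grid = np.ix_(*[np.arange(n) for n in idx.shape]) if idx.ndim else ()
    out = x.data[(*grid, idx)] if idx.ndim else x.data[idx]

    def bw(g):
        acc = np.zeros_like(x.data)
        if idx.ndim:
            np.add.at(acc, (*grid, idx), g)
        else:
            acc[idx] += g
        x._accum(acc)

    return Tensor(out, x.requires_grad, (x,), bw)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)

    def bw(g):
        acc = np.zeros_like(table.data)
        np.add.at(acc, ids.reshape(-1), g.reshape(-1, table.shape[-1]))
        table._accum(acc)

    return Tensor(table.data[ids], table.requires_grad, (table,), bw)
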