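"""Transformer building blocks on top of the numpy autograd engine.

Implements scaled dot-product attention softmax(Q K^T / sqrt(d_k)) V,
multi-head attention with per-head projections W^Q_i, W^K_i, W^V_i and the
output projection W^O, post-norm encoder layers with a GELU feed-forward
block, AdamW, and the warm-up / flat / linear-decay learning-rate schedule.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ._autograd import Tensor, concat

__all__ = [
    "scaled_attention",
    "multi_head_attention",
    "Linear",
    "LayerNorm",
    "MultiHeadAttention",
    "EncoderLayer",
    "AdamW",
    "lr_schedule",
]


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def scaled_attention(Q, K, V, additive_mask: Optional[np.ndarray] = None) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V over the last two axes.

    ``additive_mask`` (broadcastable to the score matrix) is added to the
    scores before the softmax; use large negative values to hide padding.
    """
    Q, K, V = _t(Q), _t(K), _t(V)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"query/key dims differ: {Q.shape[-1]} vs {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("key/value lengths differ")
    d_k = Q.shape[-1]
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    if additive_mask is not None:
        scores = scores + additive_mask
    return scores.softmax() @ V


def multi_head_attention(
    Q, K, V,
    w_q: Sequence, w_k: Sequence, w_v: Sequence, w_o,
    additive_mask: Optional[np.ndarray] = None,
) -> Tensor:
    """Concatenate H projected attention heads and map them through W^O.

    ``w_q``/``w_k``/``w_v`` are per-head projection matrices; ``w_o`` maps
    the concatenation back to the model width.
    """
    heads = [
        scaled_attention(_t(Q) @ _t(wq), _t(K) @ _t(wk), _t(V) @ _t(wv),
                         additive_mask)
        for wq, wk, wv in zip(w_q, w_k, w_v)
    ]
    return concat(heads, axis=-1) @ _t(w_o)


class Module:
    """Tiny parameter-container base; subclasses register Tensors."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out


def _init(rng: np.random.Generator, *shape) -> Tensor:
    return Tensor(rng.normal(0.0, 0.02, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = _init(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gain, self.bias)


class MultiHeadAttention(Module):
    """Self-attention with fused QKV projections split into H heads."""

    def __init__(self, hidden: int, n_heads: int, rng: np.random.Generator):
        if hidden % n_heads:
            raise ValueError(f"hidden {hidden} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_k = hidden // n_heads
        self.q = Linear(hidden, hidden, rng)
        self.k = Linear(hidden, hidden, rng)
        self.v = Linear(hidden, hidden, rng)
        self.o = Linear(hidden, hidden, rng)

    def _split(self, x: Tensor) -> Tensor:
        B, L, H = x.shape
        return x.reshape(B, L, self.n_heads, self.d_k).swapaxes(1, 2)

    def __call__(self, x: Tensor, additive_mask: Optional[np.ndarray] = None) -> Tensor:
        B, L, H = x.shape
        q = self._split(self.q(x))
        k = self._split(self.k(x))
        v = self._split(self.v(x))
        out = scaled_attention(q, k, v, additive_mask)  # (B, heads, L, d_k)
        merged = out.swapaxes(1, 2).reshape(B, L, H)
        return self.o(merged)


class EncoderLayer(Module):
    """Post-norm Transformer encoder block with GELU feed-forward."""

    def __init__(self, hidden: int, n_heads: int, rng: np.random.Generator,
                 ff_mult: int = 4):
        self.attn = MultiHeadAttention(hidden, n_heads, rng)
        self.ln1 = LayerNorm(hidden)
        self.ff1 = Linear(hidden, ff_mult * hidden, rng)
        self.ff2 = Linear(ff_mult * hidden, hidden, rng)
        self.ln2 = LayerNorm(hidden)

    def __call__(self, x: Tensor, additive_mask: Optional[np.ndarray] = None) -> Tensor:
        x = self.ln1(x + self.attn(x, additive_mask))
        return self.ln2(x + self.ff2(self.ff1(x).gelu()))


class AdamW(Module):
    """Adam with decoupled weight decay (no decay on 1-D tensors)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 4e-4,
                 betas: tuple = (0.9, 0.98), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if p.data.ndim > 1 and self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= (p.data.dtype.type(lr) * update)


def lr_schedule(step: int, total_steps: int, warmup_steps: int,
                decay_steps: int) -> float:
    """Linear warm-up, flat middle, linear decay over the final steps."""
    if warmup_steps > 0 and step < warmup_steps:
        return (step + 1) / warmup_steps
    decay_start = total_steps - decay_steps
    if decay_steps > 0 and step >= decay_start:
        return max(0.0, (total_steps - step) / decay_steps)
    return 1.0
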