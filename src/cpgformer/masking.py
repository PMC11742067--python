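"""Masked-language-model corruption with neighbour expansion.

Seed tokens are selected i.i.d. at ``rate`` among non-padding positions.
Each seed draws one corruption category — 80% [MASK], 10% random 3-mer,
10% unchanged — and the category is applied to the seed *and* its
immediate left/right neighbours, all of which enter the loss (mask
indicator 1).  Masking neighbours together prevents the model from
trivially reading a masked 3-mer off its overlapping neighbours.

When groups of nearby seeds overlap, the seed with the larger index wins
(seeds are applied in increasing position order, last writer wins).
Random-replacement tokens are drawn independently per position from the
64 DNA 3-mers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vocab import Vocabulary

__all__ = ["MaskedBatch", "apply_mlm_masking"]


@dataclass
class MaskedBatch:
    """Original + corrupted token ids and the per-token loss mask."""

    original: np.ndarray       # (B, L) int
    corrupted: np.ndarray      # (B, L) int
    mask_indicator: np.ndarray  # (B, L) 0/1, where the MLM loss applies
    attention_mask: np.ndarray  # (B, L) 0/1, non-padding positions
    methyl_codes: np.ndarray   # all-zero during pre-training
    positions: np.ndarray


def apply_mlm_masking(
    token_ids: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    vocab: Vocabulary,
    attention_mask: np.ndarray | None = None,
) -> MaskedBatch:
    """Corrupt a (B, L) batch of token ids for masked-language-model training."""
    if not 0.0 < rate < 1.0:
        raise ValueError(f"mask rate must be in (0, 1), got {rate}")
    token_ids = np.atleast_2d(np.asarray(token_ids, dtype=np.int64))
    B, L = token_ids.shape
    if attention_mask is None:
        attention_mask = np.ones_like(token_ids)
    attention_mask = np.atleast_2d(attention_mask).astype(np.int64)
    eligible = attention_mask == 1

    seeds = (rng.random((B, L)) < rate) & eligible
    u = rng.random((B, L))
    category = np.where(u < 0.8, 0, np.where(u < 0.9, 1, 2))  # mask/random/keep
    kmer_ids = np.asarray(vocab.kmer_ids)
    random_tokens = kmer_ids[rng.integers(0, len(kmer_ids), size=(B, L))]

    def shift(a: np.ndarray, d: int, fill) -> np.ndarray:
        out = np.full_like(a, fill)
        if d == 0:
            return a.copy()
        if d > 0:
            out[:, d:] = a[:, :-d]
        else:
            out[:, :d] = a[:, -d:]
        return out

    # governing seed for each position = covering seed with the largest
    # index: prefer the seed at p+1, then p, then p-1
    marked = np.zeros((B, L), dtype=bool)
    governing = np.full((B, L), -1, dtype=np.int64)
    for d in (-1, 0, 1):  # ascending seed index; the last write wins
        s = shift(seeds, -d, False)  # seed at p + d covers position p
        c = shift(category, -d, 0)
        marked |= s
        governing = np.where(s, c, governing)
    marked &= eligible

    corrupted = token_ids.copy()
    corrupted[marked & (governing == 0)] = vocab.mask_id
    rand_sel = marked & (governing == 1)
    corrupted[rand_sel] = random_tokens[rand_sel]

    return MaskedBatch(
        original=token_ids,
        corrupted=corrupted,
        mask_indicator=marked.astype(np.int64),
        attention_mask=attention_mask,
        methyl_codes=np.zeros_like(token_ids),
        positions=np.tile(np.arange(L, dtype=np.int64), (B, 1)),
    )
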