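"""3-mer vocabulary and read encoding.

Reads are tokenised into overlapping 3-mers (stride 1),
so a read of length L yields L-2 tokens.  The vocabulary holds the 64 DNA
3-mers plus five special tokens (69 entries).  CpG methylation states are
attached to the token whose middle base is the called cytosine:
0 = unmethylated CpG, 1 = methylated CpG, 2 = everything else.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import EncodedRead, MethylRead

logger = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "build_vocabulary",
    "tokenize_sequence",
    "encode_methylation",
    "encode_read",
    "encode_reads",
    "NON_CPG_CODE",
]

#: methyl code for positions that are not a called CpG (and for padding)
NON_CPG_CODE = 2

_BASES = "ACGT"
_SPECIAL = ("[PAD]", "[UNK]", "[MASK]", "[CLS]", "[SEP]")


@dataclass(frozen=True)
class Vocabulary:
    """Bidirectional 3-mer <-> integer-id map with five special tokens."""

    token_to_id: dict
    id_to_token: tuple

    def __len__(self) -> int:
        return len(self.id_to_token)

    def lookup(self, token: str) -> int:
        try:
            return self.token_to_id[token]
        except KeyError:
            # 3-mers containing N (or any unknown symbol) map to [UNK]
            return self.token_to_id["[UNK]"]

    def inverse(self, token_id: int) -> str:
        return self.id_to_token[token_id]

    @property
    def pad_id(self) -> int:
        return self.token_to_id["[PAD]"]

    @property
    def unknown_id(self) -> int:
        return self.token_to_id["[UNK]"]

    @property
    def mask_id(self) -> int:
        return self.token_to_id["[MASK]"]

    @property
    def special_ids(self) -> tuple:
        return tuple(self.token_to_id[t] for t in _SPECIAL)

    @property
    def kmer_ids(self) -> tuple:
        return tuple(
            i for i, t in enumerate(self.id_to_token) if t not in _SPECIAL
        )

    def encode_tokens(self, tokens: Iterable[str]) -> np.ndarray:
        return np.fromiter((self.lookup(t) for t in tokens), dtype=np.int64)


def build_vocabulary() -> Vocabulary:
    """Return the fixed 69-entry vocabulary (5 special tokens + 64 3-mers).

    Special tokens occupy ids 0-4; the DNA 3-mers follow in lexicographic
    order (ACGT alphabet).  Idempotent: every call returns an equal map.
    """
    tokens = list(_SPECIAL) + ["".join(k) for k in itertools.product(_BASES, repeat=3)]
    return Vocabulary(
        token_to_id={t: i for i, t in enumerate(tokens)},
        id_to_token=tuple(tokens),
    )


def tokenize_sequence(sequence: str) -> list[str]:
    """Split a DNA string into overlapping 3-mers (stride 1, left to right)."""
    seq = sequence.upper()
    if len(seq) < 3:
        raise ValueError(f"sequence of length {len(seq)} is too short to tokenise")
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(invalid)}")
    return [seq[i : i + 3] for i in range(len(seq) - 2)]


def encode_methylation(read: MethylRead, tokens: Sequence[str]) -> np.ndarray:
    """Assign methylation codes to 3-mer tokens.

    The call at read offset ``o`` lands on token ``o - 1`` (the token whose
    middle base is that cytosine).  CpGs whose C is the first or last base
    of the read have no token with the C in the middle; their state cannot
    be encoded and is dropped with a log message.
    """
    if len(tokens) != len(read.sequence) - 2:
        raise ValueError("tokens do not match read.sequence (wrong length)")
    codes = np.full(len(tokens), NON_CPG_CODE, dtype=np.int64)
    n = len(read.sequence)
    for offset, methylated in read.cpg_calls:
        if offset == 0 or offset == n - 1:
            logger.debug(
                "read %s: CpG at boundary offset %d dropped from encoding",
                read.read_id,
                offset,
            )
            continue
        codes[offset - 1] = 1 if methylated else 0
    return codes


def encode_read(
    read: MethylRead,
    vocab: Vocabulary,
    seq_len: int,
) -> EncodedRead:
    """Tokenise + encode one read, padded/truncated to ``seq_len`` tokens."""
    tokens = tokenize_sequence(read.sequence)
    ids = vocab.encode_tokens(tokens)
    codes = encode_methylation(read, tokens)
    L = min(len(ids), seq_len)
    token_ids = np.full(seq_len, vocab.pad_id, dtype=np.int64)
    methyl = np.full(seq_len, NON_CPG_CODE, dtype=np.int64)
    mask = np.zeros(seq_len, dtype=np.int64)
    token_ids[:L] = ids[:L]
    methyl[:L] = codes[:L]
    mask[:L] = 1
    return EncodedRead(
        token_ids=token_ids,
        methyl_codes=methyl,
        positions=np.arange(seq_len, dtype=np.int64),
        attention_mask=mask,
        region_index=read.region_index,
    )


def encode_reads(
    reads: Sequence[MethylRead],
    vocab: Vocabulary,
    seq_len: int,
) -> dict:
    """Encode a batch of reads into stacked arrays keyed by field name."""
    enc = [encode_read(r, vocab, seq_len) for r in reads]
    return {
        "token_ids": np.stack([e.token_ids for e in enc]),
        "methyl_codes": np.stack([e.methyl_codes for e in enc]),
        "positions": np.stack([e.positions for e in enc]),
        "attention_mask": np.stack([e.attention_mask for e in enc]),
        "region_index": np.array([e.region_index for e in enc], dtype=np.int64),
    }
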