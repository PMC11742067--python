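"""Core domain containers shared across the package.

Coordinate convention: 0-based, half-open ``[start, end)`` everywhere in
memory.  BED-like tables are read as-is (they already follow this
convention); SAM/BAM records are converted by pysam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "MethylRead",
    "EncodedRead",
    "PosteriorTable",
    "PurityResult",
    "CellFractionResult",
]


@dataclass(frozen=True)
class GenomicRegion:
    """A scored genomic interval, typically a differentially methylated region.

    ``area_stat`` is the DSS areaStat score (sum of per-locus Wald statistics)
    used to rank regions; ``region_index`` is the integer id fed to the
    region embedding of the classifier.
    """

    chrom: str
    start: int
    end: int
    area_stat: float = 0.0
    region_index: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted region {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        """Base pairs shared with ``[start, end)``."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class MethylRead:
    """One sequenced molecule with its per-CpG methylation calls.

    ``cpg_calls`` is an ordered list of ``(offset, methylated)`` pairs where
    ``offset`` indexes the C of a CG dinucleotide within ``sequence`` and
    offsets are strictly increasing.
    """

    read_id: str
    chrom: str
    start: int
    sequence: str
    cpg_calls: Sequence[tuple[int, bool]]
    strand: str = "+"
    region_index: int = -1
    cell_label: Optional[str] = None

    def __post_init__(self) -> None:
        offsets = [o for o, _ in self.cpg_calls]
        if any(b >= a for a, b in zip(offsets[1:], offsets[:-1])):
            raise ValueError(f"CpG call offsets not strictly increasing: {offsets}")
        n = len(self.sequence)
        for o in offsets:
            if not 0 <= o < n:
                raise ValueError(f"CpG call offset {o} outside read of length {n}")
            if self.sequence[o] != "C":
                raise ValueError(
                    f"CpG call offset {o} is {self.sequence[o]!r}, expected 'C'"
                )
            if o + 1 < n and self.sequence[o + 1] != "G":
                raise ValueError(f"CpG call offset {o} is not followed by 'G'")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    def mean_methylation(self) -> float:
        """Fraction of methylated CpGs on this read (nan if no CpG)."""
        if not self.cpg_calls:
            return float("nan")
        return float(np.mean([m for _, m in self.cpg_calls]))


@dataclass
class EncodedRead:
    """Model-ready arrays for one read.

    All arrays share length L (the configured sequence length); padded tail
    positions carry ``attention_mask == 0``.  ``methyl_codes`` uses
    0 = unmethylated CpG, 1 = methylated CpG, 2 = non-CpG (and padding).
    """

    token_ids: np.ndarray
    methyl_codes: np.ndarray
    positions: np.ndarray
    attention_mask: np.ndarray
    region_index: int = -1

    def __post_init__(self) -> None:
        L = len(self.token_ids)
        if not (len(self.methyl_codes) == len(self.positions) == len(self.attention_mask) == L):
            raise ValueError("EncodedRead arrays must share one length")
        bad = set(np.unique(self.methyl_codes)) - {0, 1, 2}
        if bad:
            raise ValueError(f"methyl codes outside {{0,1,2}}: {sorted(bad)}")


class PosteriorTable:
    """Per-read cell-type posterior probabilities plus class priors.

    Backed by a DataFrame with columns ``read_id``, ``region_index``, one
    probability column per cell type and ``predicted_label``.  Each
    probability row sums to one (tolerance 1e-6); priors are positive and
    sum to one.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        cell_types: Sequence[str],
        priors: Sequence[float],
        tol: float = 1e-6,
    ) -> None:
        cell_types = list(cell_types)
        priors = np.asarray(priors, dtype=float)
        if len(priors) != len(cell_types):
            raise ValueError("one prior per cell type required")
        if np.any(priors <= 0) or abs(priors.sum() - 1.0) > tol:
            raise ValueError(f"priors must be positive and sum to 1, got {priors}")
        missing = [c for c in ("read_id", "region_index", *cell_types) if c not in frame]
        if missing:
            raise ValueError(f"posterior table missing columns {missing}")
        probs = frame[cell_types].to_numpy(dtype=float)
        if len(frame) and np.any(np.abs(probs.sum(axis=1) - 1.0) > tol):
            worst = np.abs(probs.sum(axis=1) - 1.0).max()
            raise ValueError(f"posterior rows must sum to 1 (worst deviation {worst:.3g})")
        frame = frame.copy()
        if "predicted_label" not in frame:
            if len(frame):
                frame["predicted_label"] = [cell_types[i] for i in probs.argmax(axis=1)]
            else:
                frame["predicted_label"] = pd.Series([], dtype=str)
        self.frame = frame
        self.cell_types = cell_types
        self.priors = priors

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def posteriors(self) -> np.ndarray:
        """(n_reads, n_cell_types) posterior matrix, column order = cell_types."""
        return self.frame[self.cell_types].to_numpy(dtype=float)

    @property
    def region_index(self) -> np.ndarray:
        return self.frame["region_index"].to_numpy(dtype=int)

    @property
    def predicted_label(self) -> np.ndarray:
        return self.frame["predicted_label"].to_numpy()


@dataclass
class PurityResult:
    """Tumour-purity estimate with optional skewness adjustment diagnostics.

    All purities live in [0, 1].  When the adjustment is applied,
    ``adjusted_delta`` is the mean of ``mapping * region_deltas`` and
    ``fisher_information`` holds one value per region; otherwise it is the
    single global value.
    """

    delta: float
    region_deltas: Optional[np.ndarray] = None
    mapping: Optional[np.ndarray] = None
    adjusted_delta: Optional[float] = None
    fisher_information: Optional[np.ndarray] = None
    skewness_before: Optional[float] = None
    skewness_after: Optional[float] = None
    grid_step: float = 1e-4
    flat_likelihood: bool = False
    region_ids: Optional[np.ndarray] = None


@dataclass
class CellFractionResult:
    """Multi-cell-type composition estimate.

    ``thetas`` are the raw per-class mixture weights from the per-class
    likelihood; ``fractions`` is the reported composition
    (proportional to theta_c * |R_c|, normalised to sum to one).
    """

    cell_types: list[str]
    thetas: np.ndarray
    read_counts: np.ndarray
    fractions: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=self.cell_types, name="fraction")
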