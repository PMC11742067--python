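"""Read-level methylome simulator.

Generates labelled tumour/normal reads over synthetic CpG-dense regions and
mixes them into pseudo-bulks with a controlled tumour fraction.  The
generative model per region i:

* a tumour mean methylation level ``d_i ~ Beta(alpha, beta)`` (beta fixed
  to 5 in the standard complexity series a0_b5..a3_b5 with
  alpha in {0.1, 1, 2, 3});
* region-level scenario: every CpG on a tumour read is methylated
  independently with probability ``d_i``; on a normal read with
  probability ``1 - d_i``;
* CpG-specific scenario: tumour reads use ``d_i`` at odd-indexed CpGs
  (1-based order within the region) and ``1 - d_i`` at even-indexed CpGs,
  normal reads use the opposite phase — region means of the two cell
  types then coincide while per-CpG patterns anti-correlate.

Regions are laid out on one synthetic chromosome with CpGs planted at a
fixed spacing; the remaining sequence is random but contains no accidental
CG dinucleotide, so the planted CpGs are exactly the genomic CpGs.  Reads
are placed uniformly over the valid windows; reads longer than the region
(the 500 bp setting) extend into flanking sequence whose background CpGs
are methylated at a configurable background level in both cell types.

Increasing alpha at fixed beta=5 pushes ``d_i`` towards ``1 - d_i`` and
thus shrinks the tumour/normal contrast: larger alpha = more complex
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import GenomicRegion, MethylRead

__all__ = [
    "SimConfig",
    "SimRegion",
    "MethylomeSimulator",
    "sample_region_level",
    "mix_pseudobulk",
    "sem_of_region",
]

TUMOUR = "Tumour"
NORMAL = "Normal"


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic read-level methylome.

    alpha, beta      Beta shape parameters of the tumour mean methylation
                     (the standard complexity series fixes beta = 5 and
                     sweeps alpha over {0.1, 1, 2, 3}).
    n_regions        number of CpG-dense regions (default 100)
    read_length      read length in bp (150 or 500 in the standard runs)
    coverage         reads per region per cell type
    scenario         "region_level" or "cpg_specific"
    region_length    bp per region (default 500, a CpG-island-like span)
    cpg_spacing      mean bp between planted CpGs (default 10, island-like
                     density)
    cpg_jitter       irregular inter-CpG gaps (uniform on [spacing/2,
                     3*spacing/2]), as in real CpG islands; False gives a
                     perfectly regular grid
    region_gap       bp between consecutive regions
    background_methylation
                     methylation probability of CpGs outside regions
                     (both cell types), seen only by reads that overhang
    seed             master seed; full determinism under a fixed value
    """

    alpha: float = 0.1
    beta: float = 5.0
    n_regions: int = 100
    read_length: int = 150
    coverage: int = 10
    scenario: str = "region_level"
    region_length: int = 500
    cpg_spacing: int = 10
    cpg_jitter: bool = True
    region_gap: int = 600
    background_methylation: float = 0.5
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shapes must be positive")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.read_length < 3:
            raise ValueError("read_length must be >= 3")
        if self.scenario not in ("region_level", "cpg_specific"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.cpg_spacing < 2:
            raise ValueError("cpg_spacing must be >= 2 (CpGs cannot overlap)")


@dataclass
class SimRegion:
    """One simulated region: its CpG layout and per-cell-type CpG probabilities."""

    region_index: int
    chrom: str
    start: int
    end: int
    cpg_positions: np.ndarray  # genomic positions of the C (within region)
    d: float                   # tumour mean methylation level
    probs: dict                # cell type -> per-CpG methylation probability

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def sample_region_level(
    alpha: float, beta: float, rng: np.random.Generator, size=None
) -> np.ndarray:
    """Draw tumour mean methylation level(s) ``d_i ~ Beta(alpha, beta)``."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta shapes must be positive")
    return rng.beta(alpha, beta, size=size)


def _scenario_probs(d: float, n_cpgs: int, scenario: str) -> dict:
    if scenario == "region_level":
        t = np.full(n_cpgs, d)
        n = np.full(n_cpgs, 1.0 - d)
    else:  # cpg_specific: 1-based odd CpGs get d on tumour, normal opposite
        idx = np.arange(1, n_cpgs + 1)
        t = np.where(idx % 2 == 1, d, 1.0 - d)
        n = np.where(idx % 2 == 1, 1.0 - d, d)
    return {TUMOUR: t, NORMAL: n}


class MethylomeSimulator:
    """Deterministic synthetic genome + labelled read generator.

    Construction lays out the genome and draws the per-region ``d_i``; the
    ``simulate`` / ``reads_for_region`` methods then draw reads.  All
    randomness flows from ``config.seed``.
    """

    def __init__(self, config: SimConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._build_genome(rng)
        d = sample_region_level(config.alpha, config.beta, rng, size=config.n_regions)
        self.sim_regions = [
            SimRegion(
                region_index=i,
                chrom=config.chrom,
                start=self._region_bounds[i][0],
                end=self._region_bounds[i][1],
                cpg_positions=self._region_cpgs[i],
                d=float(d[i]),
                probs=_scenario_probs(float(d[i]), len(self._region_cpgs[i]),
                                      config.scenario),
            )
            for i in range(config.n_regions)
        ]
        self._read_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1])
        )

    # -- genome -----------------------------------------------------------

    def _build_genome(self, rng: np.random.Generator) -> None:
        cfg = self.config
        flank = max(cfg.region_gap, cfg.read_length)
        block = cfg.region_length + flank
        length = flank + cfg.n_regions * block
        # plant CpGs: inside regions at cpg_spacing; in flanks at 4x spacing
        planted: list[int] = []
        self._region_bounds = []
        self._region_cpgs = []
        background: list[int] = []
        def spaced(lo: int, hi: int, spacing: int) -> list[int]:
            if not cfg.cpg_jitter:
                return list(range(lo, hi, spacing))
            out, p = [], lo
            while p < hi:
                out.append(p)
                p += int(rng.integers(max(2, spacing // 2),
                                      spacing + spacing // 2 + 1))
            return out

        pos = 0
        for i in range(cfg.n_regions):
            flank_cpgs = spaced(pos + 2, pos + flank - 2, cfg.cpg_spacing * 4)
            background.extend(flank_cpgs)
            start = pos + flank
            end = start + cfg.region_length
            cpgs = spaced(start + 2, end - 2, cfg.cpg_spacing)
            self._region_bounds.append((start, end))
            self._region_cpgs.append(np.array(cpgs, dtype=np.int64))
            planted.extend(flank_cpgs)
            planted.extend(cpgs)
            pos = end
        tail = spaced(pos + 2, pos + flank - 2, cfg.cpg_spacing * 4)
        background.extend(tail)
        planted.extend(tail)
        pos += flank
        length = pos
        planted_set = set(planted)
        g_set = {p + 1 for p in planted}
        seq = np.empty(length, dtype="<U1")
        bases = np.array(list("ACGT"))
        draws = rng.integers(0, 4, size=length)
        prev = "A"
        for i in range(length):
            if i in planted_set:
                b = "C"
            elif i in g_set:
                b = "G"
            else:
                b = bases[draws[i]]
                if prev == "C" and b == "G":
                    b = "T"  # forbid accidental CpG
            seq[i] = b
            prev = b
        self.genome = {cfg.chrom: "".join(seq)}
        self._background_cpgs = np.array(sorted(background), dtype=np.int64)
        self._all_cpgs = np.array(sorted(planted_set), dtype=np.int64)

    @property
    def regions(self) -> list[GenomicRegion]:
        """Region definitions as GenomicRegion records (areaStat = tumour/normal
        per-CpG probability gap summed over CpGs, a separability surrogate)."""
        out = []
        for sr in self.sim_regions:
            gap = float(np.abs(sr.probs[TUMOUR] - sr.probs[NORMAL]).sum())
            out.append(
                GenomicRegion(sr.chrom, sr.start, sr.end, area_stat=gap,
                              region_index=sr.region_index)
            )
        return out

    # -- reads ------------------------------------------------------------

    def reads_for_region(
        self,
        region: SimRegion,
        cell_type: str,
        coverage: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> list[MethylRead]:
        """Draw ``coverage`` reads of one cell type over one region.

        Read starts are uniform over the valid windows: fully inside the
        region when the read is shorter than the region, and covering the
        whole region (overhanging both flanks) when it is longer.
        """
        cfg = self.config
        rng = rng if rng is not None else self._read_rng
        coverage = cfg.coverage if coverage is None else coverage
        L = cfg.read_length
        lo = min(region.start, region.end - L)
        hi = max(region.start, region.end - L)
        chrom_seq = self.genome[region.chrom]
        lo = max(lo, 0)
        hi = min(hi, len(chrom_seq) - L)
        starts = rng.integers(lo, hi + 1, size=coverage)
        reads = []
        for j, s in enumerate(starts):
            s = int(s)
            in_win = (region.cpg_positions >= s) & (region.cpg_positions < s + L)
            cpg_idx = np.nonzero(in_win)[0]
            pos = region.cpg_positions[cpg_idx]
            p = region.probs[cell_type][cpg_idx]
            bg = self._background_cpgs[
                (self._background_cpgs >= s) & (self._background_cpgs < s + L)
            ]
            all_pos = np.concatenate([pos, bg])
            all_p = np.concatenate([p, np.full(len(bg), cfg.background_methylation)])
            order = np.argsort(all_pos)
            states = rng.random(len(all_pos)) < all_p
            calls = [
                (int(all_pos[k] - s), bool(states[k])) for k in order
            ]
            reads.append(
                MethylRead(
                    read_id=f"{cell_type}_r{region.region_index}_{j}",
                    chrom=region.chrom,
                    start=s,
                    sequence=chrom_seq[s : s + L],
                    cpg_calls=calls,
                    region_index=region.region_index,
                    cell_label=cell_type,
                )
            )
        return reads

    def simulate(
        self, cell_types: Sequence[str] = (TUMOUR, NORMAL)
    ) -> dict:
        """Full pool: ``coverage`` reads per region per cell type."""
        return {
            ct: [
                read
                for sr in self.sim_regions
                for read in self.reads_for_region(sr, ct)
            ]
            for ct in cell_types
        }


def simulate_reads(
    region: SimRegion,
    cell_type: str,
    config: SimConfig,
    rng: np.random.Generator,
    simulator: Optional[MethylomeSimulator] = None,
) -> list[MethylRead]:
    """Functional wrapper over :meth:`MethylomeSimulator.reads_for_region`."""
    sim = simulator if simulator is not None else MethylomeSimulator(config)
    return sim.reads_for_region(region, cell_type, rng=rng)


def mix_pseudobulk(
    tumour_pool: Sequence[MethylRead],
    normal_pool: Sequence[MethylRead],
    tumour_fraction: float,
    n_reads: int,
    rng: np.random.Generator,
    replace: bool = False,
) -> tuple[list[MethylRead], dict]:
    """Mix labelled pools at a controlled tumour fraction.

    Exactly ``round(n_reads * tumour_fraction)`` tumour reads are drawn,
    the remainder normal, without replacement unless ``replace``.  Returns
    the shuffled mixture and a ground-truth record.
    """
    if not 0.0 <= tumour_fraction <= 1.0:
        raise ValueError("tumour_fraction must be in [0, 1]")
    n_t = int(round(n_reads * tumour_fraction))
    n_n = n_reads - n_t
    if not replace and (n_t > len(tumour_pool) or n_n > len(normal_pool)):
        raise ValueError(
            f"requested {n_t}+{n_n} reads exceed pool sizes "
            f"{len(tumour_pool)}/{len(normal_pool)} without replacement"
        )
    if n_t > 0 and not tumour_pool:
        raise ValueError("empty tumour pool with positive tumour share")
    if n_n > 0 and not normal_pool:
        raise ValueError("empty normal pool with positive normal share")
    idx_t = rng.choice(len(tumour_pool), size=n_t, replace=replace) if n_t else []
    idx_n = rng.choice(len(normal_pool), size=n_n, replace=replace) if n_n else []
    mixture = [tumour_pool[i] for i in idx_t] + [normal_pool[i] for i in idx_n]
    rng.shuffle(mixture)
    truth = {
        "tumour_fraction": n_t / n_reads if n_reads else 0.0,
        "requested_fraction": tumour_fraction,
        "n_tumour": n_t,
        "n_normal": n_n,
    }
    return mixture, truth


def sem_of_region(reads: Sequence[MethylRead]) -> float:
    """Standard error of the mean of per-read mean methylation levels.

    Reads without CpGs carry no methylation signal and are excluded; at
    least two informative reads are required.
    """
    means = np.array(
        [r.mean_methylation() for r in reads if len(r.cpg_calls) > 0], dtype=float
    )
    if len(means) < 2:
        raise ValueError("SEM needs at least two reads with CpGs")
    return float(np.std(means, ddof=1) / np.sqrt(len(means)))
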