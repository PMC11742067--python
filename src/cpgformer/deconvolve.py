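"""Purity and cell-type-fraction estimation from per-read posteriors.

The chain for two classes (tumour T / normal N): posterior inversion
``P(r|c) ∝ P(c|r) / P(c)`` (every read assumed to share one marginal, so
the omitted factor is a per-read constant), a single-parameter mixture
log-likelihood

    log L(δ) = Σ_i log[ δ · s_i(T) + (1 − δ) · s_i(N) ],

maximised by grid search (step 1e-4 over [0, 1], ties to the smallest δ),
region-wise purities δ_k, a skewness-minimising remapping W of the δ_k
(adjustment for unevenly distributed tumour reads), and the Fisher
information — the variance over reads of the score
``(s_T − s_N) / (δ s_T + (1 − δ) s_N)`` — as a precision report.

Scores are normalised per read by their maximum before use; the
likelihood argmax is invariant to any per-read rescaling, and the
normalised scores stay in (0, 1], which keeps the log-domain evaluation
well behaved.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .types import CellFractionResult, MethylRead, PosteriorTable, PurityResult

logger = logging.getLogger(__name__)

__all__ = [
    "invert_posteriors",
    "purity_mle",
    "region_purities",
    "skewness_g1",
    "adjust_estimate",
    "fisher_information",
    "cell_fractions",
    "reconstruct_methylation",
    "PurityEstimator",
    "CellFractionEstimator",
]


def invert_posteriors(
    table: PosteriorTable, normalise: bool = True
) -> np.ndarray:
    """Per-read class-conditional scores ``P(c|r) / P(c)``.

    The true ``P(r|c)`` differs from this by a per-read constant (the
    marginal), which cancels from every argmax over mixture weights.
    With ``normalise`` each row is divided by its maximum.
    """
    priors = np.asarray(table.priors, dtype=float)
    if np.any(priors <= 0):
        raise ValueError("class priors must be strictly positive")
    scores = table.posteriors / priors[None, :]
    if normalise:
        mx = scores.max(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(mx > 0, scores / mx, scores)
    return scores


def _grid(grid_step: float) -> np.ndarray:
    n = int(round(1.0 / grid_step))
    return np.linspace(0.0, 1.0, n + 1)


def _grid_loglik(scores: np.ndarray, grid: np.ndarray,
                 chunk: int = 256) -> np.ndarray:
    s_t, s_n = scores[:, 0], scores[:, 1]
    out = np.empty(len(grid))
    with np.errstate(divide="ignore"):
        for i in range(0, len(grid), chunk):
            g = grid[i : i + chunk, None]
            out[i : i + chunk] = np.log(
                g * s_t[None, :] + (1.0 - g) * s_n[None, :]
            ).sum(axis=1)
    return out


def purity_mle(
    scores: np.ndarray, grid_step: float = 1e-4
) -> tuple[float, bool]:
    """Grid-search MLE of the tumour fraction from (N, 2) scores.

    Returns ``(delta_hat, flat)`` where ``flat`` flags a likelihood that
    is constant over the whole grid (all reads uninformative); ties are
    broken toward the smallest δ.  Reads with both scores zero are
    dropped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be (n_reads, 2): tumour, normal")
    dead = (scores == 0).all(axis=1)
    if dead.any():
        logger.warning("dropping %d reads with all-zero scores", dead.sum())
        scores = scores[~dead]
    if len(scores) == 0:
        raise ValueError("no informative reads")
    grid = _grid(grid_step)
    ll = _grid_loglik(scores, grid)
    finite = ll[np.isfinite(ll)]
    flat = len(finite) > 0 and (finite.max() - finite.min()) < 1e-10 \
        and len(finite) == len(ll)
    return float(grid[np.argmax(ll)]), bool(flat)


def region_purities(
    scores: np.ndarray,
    region_index: np.ndarray,
    grid_step: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent purity MLE per region; empty regions are excluded."""
    region_index = np.asarray(region_index)
    ids = np.unique(region_index)
    deltas = np.empty(len(ids))
    for j, rid in enumerate(ids):
        deltas[j], _ = purity_mle(scores[region_index == rid], grid_step)
    return ids, deltas


def skewness_g1(values: Sequence[float]) -> float:
    """Adjusted Fisher-Pearson standardised third moment G1.

    ``G1 = m3 sqrt(K(K-1)) / (m2^{3/2} (K-2))`` with central moments about
    the sample mean.  Requires K >= 3 and non-zero variance.
    """
    x = np.asarray(values, dtype=float)
    K = len(x)
    if K < 3:
        raise ValueError("skewness needs at least three values")
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    m3 = ((x - mu) ** 3).mean()
    if m2 <= 0:
        raise ValueError("skewness undefined for zero variance")
    return float(m3 * np.sqrt(K * (K - 1)) / (m2 ** 1.5 * (K - 2)))


def _g1_safe(x: np.ndarray) -> float:
    """G1 treating a (near-)constant sample as perfectly symmetric."""
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    if m2 < 1e-24:
        return 0.0
    m3 = ((x - mu) ** 3).mean()
    K = len(x)
    return float(m3 * np.sqrt(K * (K - 1)) / (m2 ** 1.5 * (K - 2)))


def adjust_estimate(
    region_deltas: np.ndarray,
    deformation_penalty: float = 0.1,
) -> tuple[np.ndarray, float, dict]:
    """Skewness-minimising remapping of region-wise purities.

    Finds the mapping ``W`` that minimises the skewness of the mapped
    purities, ``G1(W ∘ δ)²``, subject to ``W_k δ_k ∈ [0, 1]``, starting
    from the identity ``W = 1`` (box-constrained L-BFGS-B on all
    coordinates at once).  Zeroing the skewness by rescaling alone is
    under-determined — many mappings symmetrise the distribution, and
    some of them deform it wildly — so a small quadratic penalty
    ``deformation_penalty * mean((W_k δ_k − δ_k)²)`` selects the
    symmetrising mapping closest to the identity.  Returns
    ``(W_hat, adjusted_delta, info)`` with ``adjusted_delta`` the mean of
    the mapped purities; the attained G1² never exceeds the initial one
    (the identity is a feasible start).

    All-equal ``δ`` (skewness undefined) returns the identity mapping.
    """
    delta = np.asarray(region_deltas, dtype=float)
    K = len(delta)
    if K < 3:
        raise ValueError("adjustment needs at least three regions")
    if np.ptp(delta) == 0.0:
        return np.ones(K), float(delta[0]), {
            "g1_before": None, "g1_after": None, "n_iter": 0}
    g1_before = _g1_safe(delta)
    bounds = [(0.0, 1.0 / d) if d > 0 else (0.0, 1.0) for d in delta]
    lam = deformation_penalty

    def objective(w: np.ndarray) -> float:
        mapped = w * delta
        return _g1_safe(mapped) ** 2 + lam * np.mean((mapped - delta) ** 2)

    res = minimize(objective, x0=np.ones(K), bounds=bounds, method="L-BFGS-B")
    W = res.x
    mapped = W * delta
    info = {"g1_before": g1_before, "g1_after": _g1_safe(mapped),
            "n_iter": int(res.nit)}
    return W, float(mapped.mean()), info


def fisher_information(
    scores: np.ndarray, delta: float, ddof: int = 1
) -> float:
    """Variance over reads of the per-read score (derivative of the
    per-read log-likelihood in δ); reads with a zero mixture denominator
    are excluded with a warning."""
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie strictly inside (0, 1)")
    scores = np.asarray(scores, dtype=float)
    denom = delta * scores[:, 0] + (1.0 - delta) * scores[:, 1]
    ok = denom > 0
    if not ok.all():
        logger.warning("excluding %d reads with zero denominator",
                       (~ok).sum())
    s = (scores[ok, 0] - scores[ok, 1]) / denom[ok]
    if len(s) < 2:
        return 0.0
    return float(np.var(s, ddof=ddof))


def cell_fractions(
    table: PosteriorTable, grid_step: float = 1e-4
) -> CellFractionResult:
    """Multi-class composition from classified reads.

    For each class c, with R_c the reads classified into c and P(r|c) the
    inverted score re-normalised per read to sum to one over classes,
    θ_c maximises Π_{r in R_c} [θ_c P(r|c) + (1-θ_c)(1-P(r|c))] on the
    grid.  Because every θ_c approaches 1 under a confident classifier,
    the reported composition is fraction_c ∝ θ_c · |R_c|, normalised to
    sum to one (the read-count fraction in the certainty limit).  Classes
    with no classified reads get fraction 0.
    """
    if len(table) == 0:
        raise ValueError("empty posterior table")
    scores = invert_posteriors(table, normalise=False)
    scores = scores / scores.sum(axis=1, keepdims=True)
    labels = table.predicted_label
    grid = _grid(grid_step)
    thetas = np.zeros(len(table.cell_types))
    counts = np.zeros(len(table.cell_types), dtype=int)
    for c, name in enumerate(table.cell_types):
        in_c = labels == name
        counts[c] = in_c.sum()
        if counts[c] == 0:
            thetas[c] = 0.0
            continue
        p = scores[in_c, c]
        with np.errstate(divide="ignore"):
            ll = np.array([
                np.log(g * p + (1.0 - g) * (1.0 - p)).sum() for g in grid
            ])
        thetas[c] = grid[np.argmax(ll)]
    weights = thetas * counts
    total = weights.sum()
    fractions = weights / total if total > 0 else np.zeros_like(weights)
    return CellFractionResult(
        cell_types=list(table.cell_types),
        thetas=thetas,
        read_counts=counts,
        fractions=fractions,
    )


def reconstruct_methylation(
    reads: Sequence[MethylRead],
    predicted_labels: Sequence[str],
    cell_types: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-region, per-class mean methylation of classified reads.

    Rows = region index, columns = predicted class; each cell is the mean
    over assigned reads of the per-read methylated-CpG fraction.  A class
    with no reads in a region is missing (NaN), not zero.  Reads without
    CpGs are skipped.
    """
    rows = [
        {"region_index": r.region_index, "label": lab,
         "level": r.mean_methylation()}
        for r, lab in zip(reads, predicted_labels)
        if len(r.cpg_calls) > 0
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    out = df.pivot_table(index="region_index", columns="label",
                         values="level", aggfunc="mean")
    if cell_types is not None:
        out = out.reindex(columns=list(cell_types))
    out.columns.name = None
    return out


# ---------------------------------------------------------------------------
# Estimators


class PurityEstimator(BaseEstimator):
    """Tumour-purity estimator over a two-class posterior table.

    Parameters
    ----------
    adjust : apply the skewness-minimising remapping of region-wise
        purities; the final estimate is then the mean mapped purity and
        the Fisher information is reported per region.
    grid_step : grid resolution of the likelihood search (default 1e-4).
    tumour_label : name of the tumour column in the posterior table.

    Fitted attributes: ``delta_`` (global MLE), ``region_ids_``,
    ``region_deltas_``, ``mapping_``, ``adjusted_delta_``,
    ``fisher_information_``, ``skewness_before_``/``skewness_after_``,
    ``flat_likelihood_`` and ``result_`` (a :class:`PurityResult`).
    ``estimate_`` is the headline number (adjusted when adjustment is on).
    """

    def __init__(self, adjust: bool = True, grid_step: float = 1e-4,
                 tumour_label: str = "Tumour"):
        self.adjust = adjust
        self.grid_step = grid_step
        self.tumour_label = tumour_label

    def fit(self, table: PosteriorTable, y=None) -> "PurityEstimator":
        if len(table.cell_types) != 2:
            raise ValueError("purity estimation needs exactly two cell types")
        if self.tumour_label not in table.cell_types:
            raise ValueError(f"{self.tumour_label!r} not among cell types")
        t = table.cell_types.index(self.tumour_label)
        order = [t, 1 - t]
        scores = invert_posteriors(table)[:, order]
        self.delta_, self.flat_likelihood_ = purity_mle(scores, self.grid_step)
        self.region_ids_, self.region_deltas_ = region_purities(
            scores, table.region_index, self.grid_step)
        if self.adjust and len(self.region_deltas_) >= 3:
            self.mapping_, self.adjusted_delta_, info = adjust_estimate(
                self.region_deltas_)
            self.skewness_before_ = info["g1_before"]
            self.skewness_after_ = info["g1_after"]
            fis = []
            for rid, dk in zip(self.region_ids_, self.region_deltas_):
                dk_in = min(max(dk, self.grid_step), 1.0 - self.grid_step)
                fis.append(fisher_information(
                    scores[table.region_index == rid], dk_in))
            self.fisher_information_ = np.asarray(fis)
            self.estimate_ = self.adjusted_delta_
        else:
            self.mapping_ = None
            self.adjusted_delta_ = None
            self.skewness_before_ = None
            self.skewness_after_ = None
            d_in = min(max(self.delta_, self.grid_step), 1.0 - self.grid_step)
            self.fisher_information_ = np.asarray(
                [fisher_information(scores, d_in)])
            self.estimate_ = self.delta_
        self.result_ = PurityResult(
            delta=self.delta_,
            region_deltas=self.region_deltas_,
            mapping=self.mapping_,
            adjusted_delta=self.adjusted_delta_,
            fisher_information=self.fisher_information_,
            skewness_before=self.skewness_before_,
            skewness_after=self.skewness_after_,
            grid_step=self.grid_step,
            flat_likelihood=self.flat_likelihood_,
            region_ids=self.region_ids_,
        )
        return self


class CellFractionEstimator(BaseEstimator):
    """Multi-cell-type composition estimator over a posterior table.

    Fitted attributes: ``thetas_``, ``read_counts_``, ``fractions_`` and
    ``result_`` (a :class:`CellFractionResult`).
    """

    def __init__(self, grid_step: float = 1e-4):
        self.grid_step = grid_step

    def fit(self, table: PosteriorTable, y=None) -> "CellFractionEstimator":
        res = cell_fractions(table, self.grid_step)
        self.cell_types_ = res.cell_types
        self.thetas_ = res.thetas
        self.read_counts_ = res.read_counts
        self.fractions_ = res.fractions
        self.result_ = res
        return self
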