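"""Two-state hidden-Markov baseline read classifier.

One HMM per cell type over the ordered CpG states of a read (observation
alphabet {unmethylated, methylated}; hidden alphabet {not differentially
methylated, differentially methylated}; inter-CpG genomic distance is
ignored).  Models are fitted by Baum-Welch on each cell type's reads with
several seeded random restarts; a read is assigned to the cell type whose
model gives the larger forward-algorithm log-likelihood (ties go to the
designated normal class).  Log-likelihood differences are converted to
pseudo-posteriors by normalised exponentiation so the output feeds the
same deconvolution machinery as the Transformer classifier.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from hmmlearn.hmm import CategoricalHMM
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .types import MethylRead, PosteriorTable

__all__ = ["fit_hmm", "classify_read_hmm", "HmmReadClassifier"]


def _observations(reads: Sequence[MethylRead]) -> tuple[np.ndarray, list[int]]:
    seqs, lengths = [], []
    for r in reads:
        if len(r.cpg_calls) < 1:
            continue
        seqs.extend(int(m) for _, m in r.cpg_calls)
        lengths.append(len(r.cpg_calls))
    return np.array(seqs, dtype=np.int64).reshape(-1, 1), lengths


def fit_hmm(
    reads: Sequence[MethylRead],
    seed: int = 0,
    n_restarts: int = 5,
    n_iter: int = 100,
) -> CategoricalHMM:
    """Baum-Welch fit of a 2-state/2-symbol HMM on one cell type's reads.

    ``n_restarts`` seeded random initialisations are run and the model
    with the best training log-likelihood kept.  Reads without CpGs are
    skipped; at least one read with >= 2 CpGs is required.
    """
    obs, lengths = _observations(reads)
    if not lengths or max(lengths) < 2:
        raise ValueError("HMM fitting needs at least one read with >= 2 CpGs")
    best_model, best_score = None, -np.inf
    for k in range(n_restarts):
        model = CategoricalHMM(
            n_components=2, n_features=2, n_iter=n_iter, tol=1e-4,
            random_state=seed * 1000 + k,
        )
        model.fit(obs, lengths)
        score = model.score(obs, lengths)
        if score > best_score:
            best_model, best_score = model, score
    return best_model


def classify_read_hmm(
    models: dict,
    read: MethylRead,
    normal_label: str = "Normal",
) -> tuple[Optional[str], float]:
    """Label a read by the larger forward likelihood; ties go to normal.

    Returns ``(label, log_likelihood_ratio)`` with the ratio oriented as
    best-vs-rest; a read without CpGs is unclassifiable -> (None, nan).
    """
    if len(read.cpg_calls) == 0:
        return None, float("nan")
    obs = np.array([[int(m)] for _, m in read.cpg_calls], dtype=np.int64)
    lls = {label: m.score(obs) for label, m in models.items()}
    ordered = sorted(lls.items(), key=lambda kv: -kv[1])
    (top, top_ll), (second, second_ll) = ordered[0], ordered[1]
    if top_ll == second_ll:  # exact tie (possibly both -inf)
        if normal_label in (top, second):
            top = normal_label
        return top, 0.0
    return top, top_ll - second_ll


class HmmReadClassifier(BaseEstimator, ClassifierMixin):
    """Per-cell-type HMM baseline with the classifier interface.

    ``fit(X, y)`` trains one HMM per class on its reads; ``predict_proba``
    returns softmax-normalised per-read log-likelihoods, so downstream
    purity estimation can consume this classifier and the Transformer
    interchangeably.  Reads without CpGs get uniform posteriors.
    """

    def __init__(self, n_restarts: int = 5, n_iter: int = 100,
                 normal_label: str = "Normal", random_state: int = 0):
        self.n_restarts = n_restarts
        self.n_iter = n_iter
        self.normal_label = normal_label
        self.random_state = random_state

    def fit(self, X: Sequence[MethylRead], y) -> "HmmReadClassifier":
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.models_ = {}
        for i, label in enumerate(self.classes_):
            members = [r for r, lab in zip(X, y) if lab == label]
            self.models_[label] = fit_hmm(
                members, seed=self.random_state + i,
                n_restarts=self.n_restarts, n_iter=self.n_iter)
        counts = np.array([(y == c).sum() for c in self.classes_], dtype=float)
        self.priors_ = counts / counts.sum()
        return self

    def _loglik_matrix(self, X: Sequence[MethylRead]) -> np.ndarray:
        check_is_fitted(self, "models_")
        out = np.zeros((len(X), len(self.classes_)))
        for i, read in enumerate(X):
            if len(read.cpg_calls) == 0:
                continue  # row of zeros -> uniform posterior
            obs = np.array([[int(m)] for _, m in read.cpg_calls],
                           dtype=np.int64)
            for j, label in enumerate(self.classes_):
                out[i, j] = self.models_[label].score(obs)
        return out

    def predict_proba(self, X: Sequence[MethylRead]) -> np.ndarray:
        ll = self._loglik_matrix(X)
        z = ll - ll.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: Sequence[MethylRead]) -> np.ndarray:
        ll = self._loglik_matrix(X)
        # ties (including zero-CpG reads) resolve to the normal class
        normal_j = (list(self.classes_).index(self.normal_label)
                    if self.normal_label in self.classes_ else 0)
        best = ll.max(axis=1, keepdims=True)
        is_best = ll == best
        pred = ll.argmax(axis=1)
        tie = is_best.sum(axis=1) > 1
        pred[tie & is_best[:, normal_j]] = normal_j
        return self.classes_[pred]

    def posterior_table(self, X: Sequence[MethylRead]) -> PosteriorTable:
        probs = self.predict_proba(X)
        frame = pd.DataFrame(probs, columns=list(self.classes_))
        frame.insert(0, "read_id", [r.read_id for r in X])
        frame.insert(1, "region_index", [r.region_index for r in X])
        frame["predicted_label"] = self.predict(X)
        return PosteriorTable(frame, list(self.classes_), self.priors_)
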