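"""Training objectives: MLM cross-entropy, read-label cross-entropy, focal loss.

All losses are sum-reduced over their batch (the trainer rescales by batch
size before the optimiser step).
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, gather_last
from .masking import MaskedBatch

__all__ = ["mlm_loss", "finetune_loss", "focal_loss"]


def mlm_loss(logits: Tensor, batch: MaskedBatch) -> Tensor:
    """Categorical cross-entropy over masked tokens only.

    ``logits`` has shape (B, L, vocab); tokens with mask indicator 0
    contribute nothing.
    """
    logp = logits.log_softmax()
    gold = gather_last(logp, batch.original)  # (B, L)
    return -(gold * batch.mask_indicator.astype(float)).sum()


def finetune_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Softmax cross-entropy on integer class labels, sum over reads."""
    labels = np.asarray(labels, dtype=np.int64)
    n_classes = logits.shape[-1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(
            f"label outside the model's class set 0..{n_classes - 1}"
        )
    return -gather_last(logits.log_softmax(), labels).sum()


def focal_loss(
    activations: Tensor,
    labels: np.ndarray,
    gamma: float = 2.0,
    alpha_f: float = 0.1,
) -> Tensor:
    """Focal loss on per-class sigmoid activations (Lin et al. form).

    With p = sigmoid(x) the per-(read, class) contribution is
    ``-alpha_f * (1-p)^gamma * log p`` for the read's own cell type and
    ``-(1-alpha_f) * p^gamma * log(1-p)`` for every other cell type;
    summed over reads and classes.  At gamma = 0, alpha_f = 0.5 this is
    exactly half the sigmoid cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if not 0.0 < alpha_f < 1.0:
        raise ValueError("alpha_f must be in (0, 1)")
    labels = np.asarray(labels, dtype=np.int64)
    n_classes = activations.shape[-1]
    onehot = np.eye(n_classes)[labels]  # (B, C)
    # stable pieces: p = sigmoid(x), 1-p = sigmoid(-x),
    # -log p = softplus(-x), -log(1-p) = softplus(x)
    x = activations
    pos = (-x).sigmoid().pow(gamma) * (-x).softplus() * alpha_f
    neg = x.sigmoid().pow(gamma) * x.softplus() * (1.0 - alpha_f)
    per_entry = pos * onehot + neg * (1.0 - onehot)
    return per_entry.sum()
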