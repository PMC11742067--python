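"""Read-level methylation classifier: encoder, pre-training and fine-tuning.

The encoder sums three embeddings per position — 3-mer token, methylation
code (0/1/2) and position — and runs them through a stack of Transformer
encoder layers.  Masked-language-model pre-training on reference-genome
segments uses token embeddings only (the methylation contribution is
forced to zero, since a reference genome carries no methylation states).
Fine-tuning appends a learned per-region channel to the encoder output
(the region index is embedded into a vector of length ``seq_len``, one
scalar per position), mean-pools over non-padding positions and applies a
two-layer feed-forward head to produce per-read cell-type logits.

``TransformerReadClassifier`` wraps the whole procedure as a
scikit-learn-style estimator (``fit`` / ``predict`` / ``predict_proba``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._autograd import Tensor, concat, embedding, no_grad
from .losses import finetune_loss, focal_loss, mlm_loss
from .masking import MaskedBatch, apply_mlm_masking
from .nn import AdamW, EncoderLayer, LayerNorm, Linear, Module, lr_schedule
from .types import MethylRead, PosteriorTable
from .vocab import Vocabulary, build_vocabulary, encode_reads, tokenize_sequence

__all__ = [
    "ModelConfig",
    "ReadEncoderModel",
    "pretrain",
    "finetune",
    "TransformerReadClassifier",
]

NEG_INF = -1e9


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation hyper-parameters.

    The full-scale preset mirrors the published setting (12 layers, 12
    heads, hidden 768, 510-token pre-training, 120k steps with 10k warm-up
    and 20k final decay, AdamW lr 4e-4, betas (0.9, 0.98), weight decay
    0.01, batch 256 with 4-step gradient accumulation, 15% mask seeding).
    The tiny preset (2 layers, 2 heads, hidden 64) is the first-class
    desk-scale configuration used throughout the tests.
    """

    n_layers: int = 2
    n_heads: int = 2
    hidden: int = 64
    seq_len: int = 150
    lr: float = 4e-4
    betas: tuple = (0.9, 0.98)
    weight_decay: float = 0.01
    pretrain_steps: int = 300
    warmup_steps: int = 30
    decay_steps: int = 50
    finetune_steps: int = 600
    batch_size: int = 32
    grad_accum: int = 1
    mask_rate: float = 0.15
    eval_interval: int = 10
    n_region_slots: int = 128
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden % self.n_heads:
            raise ValueError("hidden size must be divisible by n_heads")
        if not 0.0 < self.mask_rate < 1.0:
            raise ValueError("mask rate must be in (0, 1)")

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        return cls(**overrides)

    @classmethod
    def paper_base(cls, **overrides) -> "ModelConfig":
        base = dict(
            n_layers=12, n_heads=12, hidden=768, seq_len=510,
            pretrain_steps=120_000, warmup_steps=10_000, decay_steps=20_000,
            batch_size=256, grad_accum=4, finetune_steps=600,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def paper_500bp(cls, **overrides) -> "ModelConfig":
        return cls.paper_base(n_layers=6, seq_len=510, **overrides)

    @classmethod
    def paper_leukocyte(cls, **overrides) -> "ModelConfig":
        return cls.paper_base(n_layers=4, seq_len=160, **overrides)


class ReadEncoderModel(Module):
    """Encoder + MLM head + region-aware classifier head."""

    def __init__(self, config: ModelConfig, vocab: Optional[Vocabulary] = None):
        self.config = config
        self.vocab = vocab if vocab is not None else build_vocabulary()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
        h, L = config.hidden, config.seq_len
        V = len(self.vocab)
        init = lambda *s: Tensor(rng.normal(0, 0.02, s), requires_grad=True)
        self.token_emb = init(V, h)
        self.methyl_emb = init(3, h)
        self.pos_emb = init(L, h)
        self.ln_emb = LayerNorm(h)
        self.layers = [EncoderLayer(h, config.n_heads, rng)
                       for _ in range(config.n_layers)]
        self.mlm_head = Linear(h, V, rng)
        # row 0 of the region table is the reserved "unknown region" slot
        self.region_emb = init(config.n_region_slots + 1, L)
        self.cls_hidden = Linear(h + 1, h, rng)
        self.cls_out = Linear(h, config.n_classes, rng)

    # -- forward passes ---------------------------------------------------

    def embed_inputs(
        self,
        token_ids: np.ndarray,
        methyl_codes: np.ndarray,
        use_methylation: bool = True,
    ) -> Tensor:
        """Sum token, methylation and position embeddings, then layer-norm.

        ``use_methylation=False`` (pre-training mode) multiplies the
        methylation contribution by zero, making the output exactly
        independent of the methylation codes.
        """
        codes = np.asarray(methyl_codes)
        if codes.size and (codes.min() < 0 or codes.max() > 2):
            raise ValueError("methylation codes must lie in {0, 1, 2}")
        x = embedding(self.token_emb, np.asarray(token_ids))
        m = embedding(self.methyl_emb, codes)
        x = x + m * (1.0 if use_methylation else 0.0)
        x = x + self.pos_emb.reshape(1, *self.pos_emb.shape)
        return self.ln_emb(x)

    @staticmethod
    def _additive_mask(attention_mask: np.ndarray) -> np.ndarray:
        am = np.asarray(attention_mask)
        return np.where(am == 1, 0.0, NEG_INF)[:, None, None, :]

    def encode(
        self,
        token_ids: np.ndarray,
        methyl_codes: np.ndarray,
        attention_mask: np.ndarray,
        use_methylation: bool = True,
    ) -> Tensor:
        x = self.embed_inputs(token_ids, methyl_codes, use_methylation)
        mask = self._additive_mask(attention_mask)
        for layer in self.layers:
            x = layer(x, mask)
        return x  # (B, L, hidden)

    def mlm_logits(self, batch: MaskedBatch) -> Tensor:
        enc = self.encode(batch.corrupted, batch.methyl_codes,
                          batch.attention_mask, use_methylation=False)
        return self.mlm_head(enc)  # (B, L, vocab)

    def _region_slots(self, region_index: np.ndarray) -> np.ndarray:
        ri = np.asarray(region_index, dtype=np.int64)
        slots = ri + 1
        unknown = (ri < 0) | (ri >= self.config.n_region_slots)
        return np.where(unknown, 0, slots)

    def classify_logits(self, batch: dict) -> Tensor:
        """Per-read cell-type activations x_r for an encoded batch dict."""
        enc = self.encode(batch["token_ids"], batch["methyl_codes"],
                          batch["attention_mask"])
        B, L, h = enc.shape
        region = embedding(self.region_emb,
                           self._region_slots(batch["region_index"]))
        region = region.reshape(B, L, 1)
        x = concat([enc, region], axis=-1)  # (B, L, hidden + 1)
        am = np.asarray(batch["attention_mask"], dtype=float)[:, :, None]
        pooled = (x * am).sum(axis=1) * Tensor(1.0 / am.sum(axis=1))
        return self.cls_out(self.cls_hidden(pooled).gelu())

    def posteriors(self, batch: dict, chunk: int = 256) -> np.ndarray:
        """Softmax posteriors P(c | r), computed without building a graph."""
        out = []
        n = len(batch["token_ids"])
        with no_grad():
            for i in range(0, n, chunk):
                sub = {k: v[i : i + chunk] for k, v in batch.items()}
                out.append(self.classify_logits(sub).softmax().data)
        return np.concatenate(out, axis=0)

    # -- persistence ------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(arrays):
            raise ValueError("state does not match the model's parameter list")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.array(a, dtype=p.data.dtype)

    def save_checkpoint(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "config.json", "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=1)
        np.savez(directory / "weights.npz",
                 **{f"p{i}": a for i, a in enumerate(self.state_arrays())})

    @classmethod
    def load_checkpoint(cls, directory: Union[str, Path]) -> "ReadEncoderModel":
        directory = Path(directory)
        with open(directory / "config.json") as fh:
            cfg = json.load(fh)
        cfg["betas"] = tuple(cfg["betas"])
        model = cls(ModelConfig(**cfg))
        with np.load(directory / "weights.npz") as z:
            model.load_state_arrays([z[f"p{i}"] for i in range(len(z.files))])
        return model


def _segments_to_ids(
    segments: Sequence[str], vocab: Vocabulary, seq_len: int
) -> tuple[np.ndarray, np.ndarray]:
    ids = np.full((len(segments), seq_len), vocab.pad_id, dtype=np.int64)
    mask = np.zeros((len(segments), seq_len), dtype=np.int64)
    for i, seg in enumerate(segments):
        tok = vocab.encode_tokens(tokenize_sequence(seg))[:seq_len]
        ids[i, : len(tok)] = tok
        mask[i, : len(tok)] = 1
    return ids, mask


def pretrain(
    model: ReadEncoderModel,
    segments: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Masked-language-model pre-training on fixed-length genome segments.

    Returns the per-step loss trace (columns step, loss, lr_scale); the
    model is updated in place.  Fully deterministic given the generator.
    """
    if not segments:
        raise ValueError("empty pre-training corpus")
    cfg = model.config
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 2]))
    ids, attn = _segments_to_ids(segments, model.vocab, cfg.seq_len)
    opt = AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    rows = []
    for step in range(cfg.pretrain_steps):
        scale = lr_schedule(step, cfg.pretrain_steps, cfg.warmup_steps,
                            cfg.decay_steps)
        opt.zero_grad()
        total = 0.0
        for _ in range(cfg.grad_accum):
            take = rng.integers(0, len(ids), size=cfg.batch_size)
            batch = apply_mlm_masking(ids[take], cfg.mask_rate, rng,
                                      model.vocab, attn[take])
            loss = mlm_loss(model.mlm_logits(batch), batch)
            (loss * (1.0 / (cfg.batch_size * cfg.grad_accum))).backward()
            total += loss.item()
        opt.step(lr_scale=scale)
        rows.append({"step": step, "loss": total / cfg.grad_accum,
                     "lr_scale": scale})
    return pd.DataFrame(rows)


def _eval_classifier(model, batch, labels, loss_mode, gamma, alpha_f,
                     chunk: int = 64):
    n = len(labels)
    loss, correct = 0.0, 0
    with no_grad():
        for i in range(0, n, chunk):
            sub = {k: v[i : i + chunk] for k, v in batch.items()}
            sub_labels = labels[i : i + chunk]
            logits = model.classify_logits(sub)
            if loss_mode == "focal":
                loss += focal_loss(logits, sub_labels, gamma, alpha_f).item()
            else:
                loss += finetune_loss(logits, sub_labels).item()
            correct += int((logits.data.argmax(axis=1) == sub_labels).sum())
    return loss / max(n, 1), correct / max(n, 1)


def finetune(
    model: ReadEncoderModel,
    train_batch: dict,
    train_labels: np.ndarray,
    val_batch: Optional[dict] = None,
    val_labels: Optional[np.ndarray] = None,
    loss_mode: str = "cross_entropy",
    gamma: float = 2.0,
    alpha_f: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    restore_best: bool = True,
) -> pd.DataFrame:
    """Train the classifier head + encoder on labelled encoded reads.

    ``train_labels`` are integer class indices.  Metrics are recorded every
    ``eval_interval`` steps; when a validation split is given and
    ``restore_best`` is set, the weights of the best validation-accuracy
    step are restored at the end.
    """
    if loss_mode not in ("cross_entropy", "focal"):
        raise ValueError(f"unknown loss mode {loss_mode!r}")
    labels = np.asarray(train_labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("fine-tuning needs at least two classes present")
    cfg = model.config
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 3]))
    opt = AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    steps = cfg.finetune_steps
    warmup = max(1, steps // 10)
    n = len(labels)
    rows = []
    best = (-1.0, None)
    for step in range(steps):
        scale = lr_schedule(step, steps, warmup, 0)
        take = rng.integers(0, n, size=cfg.batch_size)
        batch = {k: v[take] for k, v in train_batch.items()}
        opt.zero_grad()
        logits = model.classify_logits(batch)
        if loss_mode == "focal":
            loss = focal_loss(logits, labels[take], gamma, alpha_f)
        else:
            loss = finetune_loss(logits, labels[take])
        (loss * (1.0 / cfg.batch_size)).backward()
        opt.step(lr_scale=scale)
        if step % cfg.eval_interval == 0 or step == steps - 1:
            tr_loss = loss.item() / cfg.batch_size
            tr_acc = float((logits.data.argmax(axis=1) == labels[take]).mean())
            rows.append({"step": step, "split": "train",
                         "loss": tr_loss, "accuracy": tr_acc})
            if val_batch is not None:
                v_loss, v_acc = _eval_classifier(
                    model, val_batch, np.asarray(val_labels, dtype=np.int64),
                    loss_mode, gamma, alpha_f)
                rows.append({"step": step, "split": "validation",
                             "loss": v_loss, "accuracy": v_acc})
                if v_acc > best[0]:
                    best = (v_acc, model.state_arrays())
    if restore_best and best[1] is not None:
        model.load_state_arrays(best[1])
    return pd.DataFrame(rows)


class TransformerReadClassifier(BaseEstimator, ClassifierMixin):
    """Cell-type classifier over reads (sequence + methylation patterns).

    Parameters mirror :class:`ModelConfig`; ``X`` is a sequence of
    :class:`MethylRead` and ``y`` their cell-type labels.  Optionally call
    :meth:`pretrain` with genome segments before :meth:`fit` to initialise
    the encoder by masked-language-model training.

    Fitted attributes: ``classes_``, ``model_``, ``priors_`` (training
    label frequencies, used later for posterior inversion), ``history_``
    (metrics trace) and ``validation_accuracy_``.
    """

    def __init__(
        self,
        n_layers: int = 2,
        n_heads: int = 2,
        hidden: int = 64,
        seq_len: int = 150,
        lr: float = 4e-4,
        weight_decay: float = 0.01,
        pretrain_steps: int = 300,
        finetune_steps: int = 600,
        batch_size: int = 32,
        mask_rate: float = 0.15,
        eval_interval: int = 10,
        loss: str = "cross_entropy",
        gamma: float = 2.0,
        alpha_f: float = 0.1,
        val_fraction: float = 0.2,
        restore_best: bool = True,
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.hidden = hidden
        self.seq_len = seq_len
        self.lr = lr
        self.weight_decay = weight_decay
        self.pretrain_steps = pretrain_steps
        self.finetune_steps = finetune_steps
        self.batch_size = batch_size
        self.mask_rate = mask_rate
        self.eval_interval = eval_interval
        self.loss = loss
        self.gamma = gamma
        self.alpha_f = alpha_f
        self.val_fraction = val_fraction
        self.restore_best = restore_best
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _config(self, n_region_slots: int, n_classes: int) -> ModelConfig:
        warmup = max(1, self.pretrain_steps // 10)
        decay = max(1, self.pretrain_steps // 6)
        return ModelConfig(
            n_layers=self.n_layers, n_heads=self.n_heads, hidden=self.hidden,
            seq_len=self.seq_len, lr=self.lr, weight_decay=self.weight_decay,
            pretrain_steps=self.pretrain_steps, warmup_steps=warmup,
            decay_steps=decay, finetune_steps=self.finetune_steps,
            batch_size=self.batch_size, mask_rate=self.mask_rate,
            eval_interval=self.eval_interval, n_region_slots=n_region_slots,
            n_classes=n_classes, seed=self.random_state,
        )

    def _encode(self, X: Sequence[MethylRead]) -> dict:
        return encode_reads(X, self.vocab_, self.seq_len)

    def pretrain(self, segments: Sequence[str]) -> "TransformerReadClassifier":
        """Run MLM pre-training; the resulting encoder initialises ``fit``."""
        self.vocab_ = build_vocabulary()
        cfg = self._config(n_region_slots=128, n_classes=2)
        model = ReadEncoderModel(cfg, self.vocab_)
        trace = pretrain(model, segments)
        self.pretrain_trace_ = trace
        self._pretrained_arrays = model.state_arrays()
        self._pretrained_config = cfg
        return self

    # -- sklearn API ------------------------------------------------------

    def fit(self, X: Sequence[MethylRead], y) -> "TransformerReadClassifier":
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to fine-tune")
        if not hasattr(self, "vocab_"):
            self.vocab_ = build_vocabulary()
        n_slots = max((r.region_index for r in X), default=-1) + 1
        cfg = self._config(n_region_slots=max(n_slots, 1),
                           n_classes=len(self.classes_))
        model = ReadEncoderModel(cfg, self.vocab_)
        if getattr(self, "_pretrained_arrays", None) is not None:
            self._transplant_encoder(model)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.random_state, 4]))
        batch = self._encode(X)
        # stratified train/validation split
        idx_train, idx_val = [], []
        for c in range(len(self.classes_)):
            members = np.flatnonzero(y_idx == c)
            members = members[rng.permutation(len(members))]
            n_val = int(round(self.val_fraction * len(members)))
            idx_val.extend(members[:n_val])
            idx_train.extend(members[n_val:])
        idx_train = np.array(sorted(idx_train))
        idx_val = np.array(sorted(idx_val))
        tr = {k: v[idx_train] for k, v in batch.items()}
        va = {k: v[idx_val] for k, v in batch.items()} if len(idx_val) else None
        y_tr, y_va = y_idx[idx_train], y_idx[idx_val] if len(idx_val) else None
        counts = np.bincount(y_tr, minlength=len(self.classes_))
        self.priors_ = counts / counts.sum()
        self.history_ = finetune(
            model, tr, y_tr, va, y_va, loss_mode=self.loss,
            gamma=self.gamma, alpha_f=self.alpha_f, rng=rng,
            restore_best=self.restore_best,
        )
        val_rows = self.history_[self.history_["split"] == "validation"]
        self.validation_accuracy_ = (
            float(val_rows["accuracy"].max()) if len(val_rows) else float("nan")
        )
        self.model_ = model
        return self

    def _transplant_encoder(self, model: ReadEncoderModel) -> None:
        """Copy pre-trained encoder weights into a (possibly differently
        headed) fine-tuning model; head/region parameters stay fresh."""
        donor = ReadEncoderModel(self._pretrained_config, self.vocab_)
        donor.load_state_arrays(self._pretrained_arrays)
        pairs = [
            (donor.token_emb, model.token_emb),
            (donor.methyl_emb, model.methyl_emb),
            (donor.pos_emb, model.pos_emb),
        ]
        pairs += list(zip(donor.ln_emb.parameters(), model.ln_emb.parameters()))
        for dl, ml in zip(donor.layers, model.layers):
            pairs += list(zip(dl.parameters(), ml.parameters()))
        for d, m in pairs:
            if d.data.shape == m.data.shape:
                m.data = d.data.copy()

    def predict_proba(self, X: Sequence[MethylRead]) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.posteriors(self._encode(X))

    def predict(self, X: Sequence[MethylRead]) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def posterior_table(self, X: Sequence[MethylRead]) -> PosteriorTable:
        """Posteriors + training priors packaged for the deconvolution stage."""
        probs = self.predict_proba(X)
        frame = pd.DataFrame(probs, columns=list(self.classes_))
        frame.insert(0, "read_id", [r.read_id for r in X])
        frame.insert(1, "region_index", [r.region_index for r in X])
        return PosteriorTable(frame, list(self.classes_), self.priors_)
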