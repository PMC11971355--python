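"""Training-set assembly and model optimization.

The central piece is k-mer balancing: class imbalance in plant CHH
methylation is so severe that a model trained on raw pools learns
k-mer-specific biases.  The balancing algorithm keeps only k-mers present
in both the positive and negative pools and draws exactly
``min(n_pos(k), n_neg(k), k_max)`` samples per side per k-mer, giving an
exact 1:1 positive:negative ratio overall and within every k-mer.

Training follows the fixed schedule: Adam (beta1=0.9, beta2=0.999),
cross-entropy loss, learning rate multiplied by 0.2 every epoch (an 80%
decay), global gradient-norm clipping, dropout between stacked layers,
and early stopping on validation accuracy.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import nn
from .model import MethylationClassifier, ModelConfig, batch_arrays
from .types import FeatureRecord


@dataclass
class LabeledPool:
    """Positive and negative feature records with per-k-mer tallies."""

    positives: list[FeatureRecord]
    negatives: list[FeatureRecord]
    k_max: int = 20_000

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    @property
    def kmer_counts_pos(self) -> Counter:
        return Counter(r.kmer for r in self.positives)

    @property
    def kmer_counts_neg(self) -> Counter:
        return Counter(r.kmer for r in self.negatives)


def balance_kmers(pool: LabeledPool, seed: int
                  ) -> tuple[list[FeatureRecord], list[FeatureRecord]]:
    """Strict per-k-mer 1:1 balancing of positive and negative samples.

    Only k-mers occurring on both sides survive; for each, the same number
    of samples — capped at ``pool.k_max`` — is drawn uniformly without
    replacement from each side.  Deterministic under ``seed``; an empty
    k-mer intersection yields two empty lists.
    """
    rng = np.random.default_rng(seed)
    by_kmer_pos: dict[str, list[FeatureRecord]] = defaultdict(list)
    by_kmer_neg: dict[str, list[FeatureRecord]] = defaultdict(list)
    for rec in pool.positives:
        by_kmer_pos[rec.kmer].append(rec)
    for rec in pool.negatives:
        by_kmer_neg[rec.kmer].append(rec)
    common = sorted(set(by_kmer_pos) & set(by_kmer_neg))
    balanced_pos: list[FeatureRecord] = []
    balanced_neg: list[FeatureRecord] = []
    for kmer in common:
        pos, neg = by_kmer_pos[kmer], by_kmer_neg[kmer]
        k_count = min(len(pos), len(neg), pool.k_max)
        take_pos = rng.choice(len(pos), size=k_count, replace=False)
        take_neg = rng.choice(len(neg), size=k_count, replace=False)
        balanced_pos.extend(pos[i] for i in take_pos)
        balanced_neg.extend(neg[i] for i in take_neg)
    return balanced_pos, balanced_neg


def split_train_test(records: Sequence[FeatureRecord], test_fraction: float,
                     seed: int) -> tuple[list[FeatureRecord], list[FeatureRecord]]:
    """Label-stratified disjoint train/test split, deterministic under seed."""
    if not records:
        raise ValueError("no records to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction {test_fraction} outside (0, 1)")
    labels = [r.label for r in records]
    if any(lab is None for lab in labels):
        raise ValueError("all records must be labeled before splitting")
    train, test = train_test_split(list(records), test_size=test_fraction,
                                   random_state=seed, stratify=labels)
    return train, test


def split_train_test_by_site(records: Sequence[FeatureRecord], test_fraction: float,
                             seed: int) -> tuple[list[FeatureRecord], list[FeatureRecord]]:
    """Split so no genomic site contributes records to both halves.

    Record-level splits leak site identity: every read at a site shares
    the site's k-mer context and label, so a model can score held-out
    records of a training site by memorization alone.  Held-out accuracy
    on site-disjoint records measures generalization to unseen contexts,
    the quantity that matters across genomes.  ``test_fraction`` applies
    to sites, not records; deterministic under ``seed``.
    """
    if not records:
        raise ValueError("no records to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction {test_fraction} outside (0, 1)")
    keys = sorted({(r.chrom, r.pos, r.strand) for r in records})
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(keys))))
    test_keys = {keys[i] for i in rng.choice(len(keys), n_test, replace=False)}
    train = [r for r in records if (r.chrom, r.pos, r.strand) not in test_keys]
    test = [r for r in records if (r.chrom, r.pos, r.strand) in test_keys]
    return train, test


@dataclass
class TrainConfig:
    """Optimization schedule.

    The learning rate at epoch e is ``lr_initial * lr_decay_per_epoch**e``
    (a decrease of 80% per epoch at the default decay of 0.2).  Initial
    rates default per encoder family: 0.001 for the Bi-LSTM, 0.0005 for
    the transformer.
    """

    lr_initial: Optional[float] = None  # resolved per encoder kind if None
    lr_decay_per_epoch: float = 0.2
    beta1: float = 0.9
    beta2: float = 0.999
    grad_clip_max_norm: float = 1.0
    early_stop_patience: int = 3
    test_fraction: float = 0.01
    batch_size: int = 256
    max_epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_initial is not None and self.lr_initial <= 0:
            raise ValueError("lr_initial must be positive")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")

    def resolve_lr(self, encoder_kind: str) -> float:
        if self.lr_initial is not None:
            return self.lr_initial
        return 0.001 if encoder_kind == "bilstm" else 0.0005

    def lr_at_epoch(self, epoch: int, encoder_kind: str) -> float:
        return self.resolve_lr(encoder_kind) * self.lr_decay_per_epoch ** epoch


@dataclass
class EpochStats:
    epoch: int
    lr: float
    train_loss: float
    train_accuracy: float
    val_accuracy: float


@dataclass
class TrainResult:
    model: MethylationClassifier
    history: list[EpochStats]
    best_epoch: int
    best_val_accuracy: float


def _accuracy(model: MethylationClassifier, records: Sequence[FeatureRecord],
              batch_size: int) -> float:
    pm = model.predict_proba(records, batch_size=batch_size)
    labels = np.array([r.label for r in records])
    return float(np.mean((pm > 0.5).astype(int) == labels))


def train_model(train: Sequence[FeatureRecord], validation: Sequence[FeatureRecord],
                model_config: ModelConfig, train_config: TrainConfig) -> TrainResult:
    """Train a classifier, tracking per-epoch history and the best checkpoint.

    Early stopping monitors validation accuracy with the configured
    patience; the returned model carries the weights of the best epoch.
    """
    if not train:
        raise ValueError("empty training set")
    labels_all = {r.label for r in train}
    if labels_all != {0, 1}:
        raise ValueError(f"training set must contain both classes, found {labels_all}")

    model = MethylationClassifier(model_config, seed=train_config.seed)
    params = model.parameters()
    optimizer = nn.Adam(params, beta1=train_config.beta1, beta2=train_config.beta2)
    rng = np.random.default_rng(train_config.seed)

    history: list[EpochStats] = []
    best_val = -np.inf
    best_epoch = -1
    best_weights: list[np.ndarray] = []
    epochs_since_best = 0
    train = list(train)
    labels = np.array([r.label for r in train])

    for epoch in range(train_config.max_epochs):
        lr = train_config.lr_at_epoch(epoch, model_config.encoder_kind)
        order = rng.permutation(len(train))
        losses = []
        correct = 0
        for lo in range(0, len(train), train_config.batch_size):
            idx = order[lo:lo + train_config.batch_size]
            batch = [train[i] for i in idx]
            codes, numeric, signal = batch_arrays(batch)
            y = labels[idx]
            logits = model.forward_logits(codes, numeric, signal,
                                          training=True, rng=rng)
            loss = nn.cross_entropy(logits, y)
            optimizer.zero_grad()
            loss.backward()
            nn.clip_grad_norm(params, train_config.grad_clip_max_norm)
            optimizer.step(lr)
            losses.append(float(loss.data))
            correct += int(((logits.data[:, 1] > logits.data[:, 0]).astype(int) == y).sum())
        val_acc = (_accuracy(model, validation, train_config.batch_size)
                   if validation else float("nan"))
        history.append(EpochStats(epoch=epoch, lr=lr,
                                  train_loss=float(np.mean(losses)),
                                  train_accuracy=correct / len(train),
                                  val_accuracy=val_acc))
        monitored = val_acc if validation else history[-1].train_accuracy
        if monitored > best_val:
            best_val = monitored
            best_epoch = epoch
            best_weights = [p.data.copy() for p in params]
            epochs_since_best = 0
        else:
            # stop once more than `patience` consecutive epochs fail to improve
            epochs_since_best += 1
            if epochs_since_best > train_config.early_stop_patience:
                break

    for p, w in zip(params, best_weights):
        p.data = w
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       best_val_accuracy=float(best_val))
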