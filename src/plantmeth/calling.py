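"""Per-read calling, adaptive thresholding, site aggregation, evaluation.

The adaptive threshold rule: per-read methylation probabilities are
binned over [0.2, 0.9) in 70 intervals of width 0.01; a well-trained
classifier pushes calls toward 0 and 1, so the least-occupied bin sits in
the valley between the two modes and its left endpoint becomes the
dataset-specific threshold P_th.  Reads with P_m >= P_th are called
methylated; per-site methylation frequency is then methylated reads over
total reads at the site, never merging strands (CHH is asymmetric).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             precision_score, recall_score, roc_auc_score)
from sklearn.neighbors import NearestNeighbors

from .types import AlignedSignalRead, ReadCall, SiteCallRecord, SiteTruth

THRESHOLD_LOW = 0.2
THRESHOLD_HIGH = 0.9
N_BINS = 70
BIN_WIDTH = 0.01


class ThresholdRangeError(ValueError):
    """No call fell inside [0.2, 0.9); callers should fall back to P_th = 0.5."""


def _probabilities(calls) -> np.ndarray:
    if len(calls) and isinstance(calls[0], ReadCall):
        return np.asarray([c.p_meth for c in calls])
    return np.asarray(calls, dtype=float)


@dataclass
class ThresholdResult:
    """Adaptive threshold with the bin occupancy profile that produced it."""

    p_th: float
    bin_edges: np.ndarray  # 70 left endpoints: 0.20, 0.21, ..., 0.89
    bin_proportions: np.ndarray  # occupancy relative to in-range calls

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges)
        self.bin_proportions = np.asarray(self.bin_proportions)
        if len(self.bin_edges) != N_BINS or len(self.bin_proportions) != N_BINS:
            raise ValueError(f"expected {N_BINS} bins")


def select_threshold(calls: Sequence[ReadCall] | np.ndarray) -> ThresholdResult:
    """Pick P_th at the left endpoint of the least-occupied probability bin.

    Proportions are relative to calls inside [0.2, 0.9); out-of-range
    calls (the confident mass near 0 and 1) do not influence the valley
    search.  Ties break toward the smallest endpoint.
    """
    pm = _probabilities(calls)
    edges = THRESHOLD_LOW + BIN_WIDTH * np.arange(N_BINS)
    in_range = pm[(pm >= THRESHOLD_LOW) & (pm < THRESHOLD_HIGH)]
    if in_range.size == 0:
        raise ThresholdRangeError(
            "no call probability falls inside [0.2, 0.9); "
            "fall back to a fixed threshold P_th = 0.5")
    bin_idx = np.minimum(((in_range - THRESHOLD_LOW) / BIN_WIDTH).astype(int), N_BINS - 1)
    counts = np.bincount(bin_idx, minlength=N_BINS)
    proportions = counts / in_range.size
    p_th = float(edges[int(np.argmin(proportions))])  # argmin takes the first minimum
    return ThresholdResult(p_th=p_th, bin_edges=edges, bin_proportions=proportions)


def call_methylation(calls: Sequence[ReadCall] | np.ndarray,
                     threshold: ThresholdResult | float) -> np.ndarray:
    """Binary per-read calls: methylated iff P_m >= P_th (inclusive)."""
    pm = _probabilities(calls)
    p_th = threshold.p_th if isinstance(threshold, ThresholdResult) else float(threshold)
    return (pm >= p_th).astype(int)


def aggregate_site_frequencies(calls: Sequence[ReadCall],
                               binary_calls: np.ndarray,
                               min_coverage: int = 10,
                               context_class: str = "CHH",
                               context_by_site: Mapping[tuple, str] | None = None
                               ) -> list[SiteCallRecord]:
    """Per-(chrom, pos, strand) methylation frequencies from read calls.

    Strands are never merged.  Sites with coverage below ``min_coverage``
    are retained but flagged unquantified.
    """
    per_site: dict[tuple, list[int]] = defaultdict(list)
    for call, state in zip(calls, binary_calls):
        per_site[call.key].append(int(state))
    records = []
    for key in sorted(per_site):
        states = per_site[key]
        chrom, pos, strand = key
        cls = context_by_site.get(key, context_class) if context_by_site else context_class
        records.append(SiteCallRecord(
            chrom=chrom, pos=pos, strand=strand, context_class=cls,
            coverage=len(states), meth_reads=sum(states),
            quantified=len(states) >= min_coverage))
    return records


def downsample_reads(reads: Sequence[AlignedSignalRead], target_depth: float,
                     genome_length: int, seed: int) -> list[AlignedSignalRead]:
    """Uniform read subset reaching (just past) a target fold-coverage.

    Reads are drawn without replacement in a seeded random order until the
    cumulative aligned bases first reach ``target_depth * genome_length``.
    If the full set is shallower than the target, all reads are returned.
    Depth is aligned bases over genome length, not a read count.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    if not reads:
        raise ValueError("empty read set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    needed = target_depth * genome_length
    picked: list[AlignedSignalRead] = []
    acc = 0.0
    for i in order:
        if acc >= needed:
            break
        read = reads[i]
        acc += read.aligned_fraction * len(read.basecalled_seq)
        picked.append(read)
    return picked if acc >= needed else list(reads)


def pearson_site_correlation(site_calls: Iterable[SiteCallRecord],
                             truth: Mapping[tuple, SiteTruth] | Iterable[SiteTruth],
                             min_cov_each: int = 5) -> tuple[float, int]:
    """Pearson r between called and BS-seq frequencies at shared sites.

    Only sites with nanopore and BS-seq coverage both at least
    ``min_cov_each`` enter; returns (r, number of evaluation sites).
    """
    if not isinstance(truth, Mapping):
        truth = {t.key: t for t in truth}
    xs, ys = [], []
    for call in site_calls:
        if call.coverage < min_cov_each:
            continue
        t = truth.get(call.key)
        if t is None or t.total_count < min_cov_each:
            continue
        xs.append(call.frequency)
        ys.append(t.frequency)
    if len(xs) < 2:
        raise ValueError(f"only {len(xs)} shared evaluation sites; correlation undefined")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("zero variance in a frequency vector; correlation undefined")
    r, _ = stats.pearsonr(xs, ys)
    return float(r), len(xs)


@dataclass
class MetricsReport:
    """Read-level evaluation metrics plus the underlying confusion counts."""

    f1: float
    accuracy: float
    recall: float
    precision: float
    auc: float
    ap: float
    tp: int
    fp: int
    tn: int
    fn: int
    pearson_r: float | None = None


def _confusion(labels: np.ndarray, predictions: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return tp, fp, tn, fn


def _metrics_once(labels: np.ndarray, probs: np.ndarray) -> MetricsReport:
    if len(set(labels.tolist())) < 2:
        raise ValueError("single-class label vector: AUC/AP undefined")
    predictions = (probs > 0.5).astype(int)  # the probability-comparison call rule
    tp, fp, tn, fn = _confusion(labels, predictions)
    return MetricsReport(
        f1=float(f1_score(labels, predictions)),
        accuracy=float(accuracy_score(labels, predictions)),
        recall=float(recall_score(labels, predictions)),
        precision=float(precision_score(labels, predictions, zero_division=0.0)),
        auc=float(roc_auc_score(labels, probs)),
        ap=float(average_precision_score(labels, probs)),
        tp=tp, fp=fp, tn=tn, fn=fn)


def single_molecule_metrics(labels: Sequence[int], probabilities: Sequence[float],
                            replicates: int = 3, seed: int = 0,
                            n_per_class: int | None = None) -> MetricsReport:
    """Balanced read-level metrics, averaged over seeded replicates.

    Each replicate draws ``n_per_class`` samples per label without
    replacement (all available when None), computes F1/accuracy/recall/
    precision from the confusion matrix and AUC/AP from the probability
    ranking, and the replicate means are reported.  Counts reported are
    from the last replicate.
    """
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probabilities, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("single-class label vector: AUC/AP undefined")
    rng = np.random.default_rng(seed)
    reports: list[MetricsReport] = []
    for _ in range(max(1, replicates)):
        if n_per_class is None:
            idx = np.arange(len(labels))
        else:
            pos_idx = np.flatnonzero(labels == 1)
            neg_idx = np.flatnonzero(labels == 0)
            take_p = rng.choice(pos_idx, size=min(n_per_class, len(pos_idx)), replace=False)
            take_n = rng.choice(neg_idx, size=min(n_per_class, len(neg_idx)), replace=False)
            idx = np.concatenate([take_p, take_n])
        reports.append(_metrics_once(labels[idx], probs[idx]))
    last = reports[-1]
    return MetricsReport(
        f1=float(np.mean([r.f1 for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        auc=float(np.mean([r.auc for r in reports])),
        ap=float(np.mean([r.ap for r in reports])),
        tp=last.tp, fp=last.fp, tn=last.tn, fn=last.fn)


def smote_oversample(minority: np.ndarray, n_new: int, k_neighbors: int = 5,
                     seed: int = 0) -> np.ndarray:
    """Synthetic minority oversampling by convex interpolation.

    Each synthetic vector is x + lambda * (x_nn - x) with lambda uniform
    in [0, 1] and x_nn one of the k nearest minority neighbors of x.
    """
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2 or len(minority) < 2:
        raise ValueError("minority set must be a 2-D array with at least 2 points")
    if len(minority) <= k_neighbors:
        raise ValueError(f"minority set of {len(minority)} points needs more than "
                         f"k_neighbors={k_neighbors}")
    if n_new == 0:
        return np.empty((0, minority.shape[1]))
    rng = np.random.default_rng(seed)
    knn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority)
    _, neighbor_idx = knn.kneighbors(minority)  # column 0 is the point itself
    base_idx = rng.integers(0, len(minority), size=n_new)
    synthetic = np.empty((n_new, minority.shape[1]))
    for row, i in enumerate(base_idx):
        j = neighbor_idx[i][1 + rng.integers(0, k_neighbors)]
        lam = rng.random()
        synthetic[row] = minority[i] + lam * (minority[j] - minority[i])
    return synthetic
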