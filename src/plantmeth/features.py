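"""Feature extraction: from filtered signal alignments to per-cytosine records.

For every candidate cytosine covered by a read, a k-mer of read bases is
taken with the target C at the center, and two matrices are built:

* a k x 5 sequence-feature matrix — per base the mean and standard
  deviation of its sampled standardized signal, its basecall quality, the
  number of raw signal samples it spans, and an integer base code
  (A=0, C=1, G=2, T=3);
* a k x 15 signal-feature matrix of standardized signal values sampled
  from the base's own signal segment.

Signal is standardized per read by median shift and MAD scale.  Minus-strand
sites are handled in the read's own 5'->3' orientation, so the feature
window always follows the direction the molecule traversed the pore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Optional

import numpy as np

from .types import (
    AlignedSignalRead,
    BASE_CODES,
    CONTEXT_CLASSES,
    CytosineSite,
    FeatureRecord,
    ReferenceGenome,
    SiteTruth,
    revcomp,
)

N_SIGNAL_SAMPLES = 15

#: BS-seq frequency thresholds for positive training sites, per CHH motif.
#: Weakly methylated motif families get progressively looser cutoffs because
#: genuinely high-methylation examples of CC*-motifs are rare in plants.
CHH_POSITIVE_THRESHOLDS: dict[str, float] = {
    "CAA": 0.95,
    "CAC": 0.90, "CAT": 0.90, "CTA": 0.90, "CTT": 0.90, "CTC": 0.90,
    "CCA": 0.85, "CCT": 0.85, "CCC": 0.85,
}
CHG_POSITIVE_THRESHOLD = 0.98
CPG_POSITIVE_THRESHOLD = 0.99
CPG_NEGATIVE_THRESHOLD = 0.02


def classify_context(trinucleotide: str) -> Optional[str]:
    """Context class of a 5'->3' trinucleotide starting with C.

    CpG takes precedence (CG*), then CHG (C-H-G), else CHH.  Returns None
    for trinucleotides that do not start with C or contain non-ACGT bases.
    """
    if len(trinucleotide) != 3 or trinucleotide[0] != "C":
        return None
    if any(b not in "ACGT" for b in trinucleotide):
        return None
    if trinucleotide[1] == "G":
        return "CpG"
    if trinucleotide[2] == "G":
        return "CHG"
    return "CHH"


def locate_motif_sites(ref: ReferenceGenome, context_class: str) -> list[CytosineSite]:
    """All cytosines of a context class, on both strands of the reference.

    A minus-strand site sits at the forward-coordinate position of its G;
    its trinucleotide is read 5'->3' on the reverse strand.  Sites whose
    3-base context window would run past a chromosome end are skipped.
    """
    if context_class not in CONTEXT_CLASSES:
        raise ValueError(f"unknown context class {context_class!r}")
    sites: list[CytosineSite] = []
    for chrom, seq in ref.chroms.items():
        n = len(seq)
        for pos in range(n):
            base = seq[pos]
            if base == "C" and pos + 3 <= n:
                tri = seq[pos:pos + 3]
                if classify_context(tri) == context_class:
                    sites.append(CytosineSite(chrom, pos, "+", context_class, tri))
            if base == "G" and pos - 2 >= 0:
                tri = revcomp(seq[pos - 2:pos + 1])
                if classify_context(tri) == context_class:
                    sites.append(CytosineSite(chrom, pos, "-", context_class, tri))
    return sites


def count_motif_kmers(k: int, context_class: str) -> int:
    """Count distinct k-mers whose central trinucleotide is of the class.

    Brute-force enumeration of all 4^k candidate k-mers, checking the class
    of the three central bases (the motif starts at index (k-3)//2, so its
    C is the first of the three central positions).  Exponential in k; used
    for the context-diversity bookkeeping at k <= 9, where it enumerates in
    well under a second.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    if context_class not in CONTEXT_CLASSES:
        raise ValueError(f"unknown context class {context_class!r}")
    start = (k - 3) // 2
    count = 0
    for kmer in product("ACGT", repeat=k):
        tri = "".join(kmer[start:start + 3])
        if classify_context(tri) == context_class:
            count += 1
    return count


@dataclass
class FilterThresholds:
    """Alignment quality gates applied before feature extraction."""

    min_mapq: int = 20
    min_aligned_fraction: float = 0.80
    min_identity: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_aligned_fraction <= 1.0:
            raise ValueError("min_aligned_fraction must be in [0, 1]")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")


@dataclass
class FilterDecision:
    keep: bool
    reason: Optional[str] = None  # "mapq" | "aligned_fraction" | "identity"


def filter_alignment(read: AlignedSignalRead,
                     thresholds: FilterThresholds = FilterThresholds()) -> FilterDecision:
    """Keep/drop decision for one alignment, with the failing gate named."""
    if read.mapq < thresholds.min_mapq:
        return FilterDecision(False, "mapq")
    if read.aligned_fraction < thresholds.min_aligned_fraction:
        return FilterDecision(False, "aligned_fraction")
    if read.identity < thresholds.min_identity:
        return FilterDecision(False, "identity")
    return FilterDecision(True)


def standardize_signal(signal: np.ndarray) -> np.ndarray:
    """Median-shift, MAD-scale standardization of a raw signal array.

    MAD is the (unscaled) median absolute deviation.  A constant signal
    (MAD = 0) standardizes to all zeros rather than dividing by zero.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("cannot standardize an empty signal array")
    med = np.median(signal)
    mad = np.median(np.abs(signal - med))
    if mad == 0.0:
        return np.zeros_like(signal)
    return (signal - med) / mad


def sample_signal_values(values: np.ndarray, n: int = N_SIGNAL_SAMPLES) -> np.ndarray:
    """Deterministically reduce or extend a base's signal to exactly n values.

    With >= n values, takes evenly spaced indices floor(j * len / n); with
    fewer, repeats the values cyclically.  Order-preserving and free of
    randomness, so features are reproducible bit-for-bit.
    """
    values = np.asarray(values, dtype=float)
    m = len(values)
    if m == 0:
        raise ValueError("base has no signal samples")
    if m >= n:
        idx = (np.arange(n) * m) // n
    else:
        idx = np.arange(n) % m
    return values[idx]


def extract_features(read: AlignedSignalRead,
                     sites: Iterable[CytosineSite] | Mapping[tuple, CytosineSite],
                     k: int = 13) -> list[FeatureRecord]:
    """FeatureRecords for every candidate site this read covers.

    Only sites on the read's own strand are observable.  The k-mer is taken
    from the read sequence (not the reference); a site is skipped when the
    center read base is not C (a basecall/alignment mismatch) or the window
    runs off the read.  Insertions contribute read bases to the window;
    deleted sites are simply not covered.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if k > len(read.basecalled_seq):
        warnings.warn(f"k={k} exceeds read length {len(read.basecalled_seq)}; "
                      "no features extracted")
        return []
    if isinstance(sites, Mapping):
        index = sites
    else:
        index = {s.key: s for s in sites}
    half = (k - 1) // 2
    std = standardize_signal(read.signal)
    seq = read.basecalled_seq
    records: list[FeatureRecord] = []
    for read_idx, ref_pos in read.aligned_pairs():
        site = index.get((read.chrom, ref_pos, read.strand))
        if site is None:
            continue
        if seq[read_idx] != "C":
            continue
        lo, hi = read_idx - half, read_idx + half + 1
        if lo < 0 or hi > len(seq):
            continue
        kmer = seq[lo:hi]
        if any(b not in BASE_CODES for b in kmer):
            continue
        seq_rows = np.empty((k, 5))
        sig_rows = np.empty((k, N_SIGNAL_SAMPLES))
        for j, base_idx in enumerate(range(lo, hi)):
            start, length = read.move_segments[base_idx]
            sampled = sample_signal_values(std[start:start + length])
            sig_rows[j] = sampled
            seq_rows[j] = (sampled.mean(), sampled.std(), read.qualities[base_idx],
                           length, BASE_CODES[seq[base_idx]])
        records.append(FeatureRecord(
            read_id=read.read_id, chrom=read.chrom, pos=ref_pos, strand=read.strand,
            kmer=kmer, seq_features=seq_rows, signal_features=sig_rows))
    return records


def select_reference_sites(truth: Mapping[tuple, SiteTruth] | Iterable[SiteTruth],
                           context_class: str,
                           min_coverage: int = 5
                           ) -> tuple[list[SiteTruth], list[SiteTruth]]:
    """High-confidence (positive, negative) training sites from BS-seq truth.

    Negatives are sites with frequency exactly zero (CpG: below 0.02);
    positives use per-motif frequency cutoffs — CHH motifs CAA > 0.95,
    CA*/CT* > 0.90, CC* > 0.85; CHG > 0.98; CpG > 0.99.  Sites below
    ``min_coverage`` BS-seq reads are excluded from both sets.
    """
    if context_class not in CONTEXT_CLASSES:
        raise ValueError(f"unknown context class {context_class!r}")
    if isinstance(truth, Mapping):
        truth = truth.values()
    positives: list[SiteTruth] = []
    negatives: list[SiteTruth] = []
    for site in truth:
        if site.context_class != context_class:
            continue
        if not site.quantified or site.total_count < min_coverage:
            continue
        freq = site.frequency
        if context_class == "CHH":
            try:
                cutoff = CHH_POSITIVE_THRESHOLDS[site.trinucleotide]
            except KeyError:
                raise ValueError(
                    f"CHH motif {site.trinucleotide!r} missing from threshold table"
                ) from None
            if freq > cutoff:
                positives.append(site)
            elif freq == 0.0:
                negatives.append(site)
        elif context_class == "CHG":
            if freq > CHG_POSITIVE_THRESHOLD:
                positives.append(site)
            elif freq == 0.0:
                negatives.append(site)
        else:  # CpG
            if freq > CPG_POSITIVE_THRESHOLD:
                positives.append(site)
            elif freq < CPG_NEGATIVE_THRESHOLD:
                negatives.append(site)
    return positives, negatives


def label_features(records: Iterable[FeatureRecord],
                   positives: Iterable[SiteTruth],
                   negatives: Iterable[SiteTruth]) -> list[FeatureRecord]:
    """Attach 1/0 labels to records at selected sites; drop the rest."""
    pos_keys = {s.key for s in positives}
    neg_keys = {s.key for s in negatives}
    labeled: list[FeatureRecord] = []
    for rec in records:
        key = (rec.chrom, rec.pos, rec.strand)
        if key in pos_keys:
            rec.label = 1
            labeled.append(rec)
        elif key in neg_keys:
            rec.label = 0
            labeled.append(rec)
    return labeled
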