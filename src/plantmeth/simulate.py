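"""Seeded synthetic nanopore methylation data.

The generator produces the statistical structure the caller assumes:
cytosine methylation shifts the raw signal level of the methylated base
and of every base whose k-mer context contains it, mirroring the adjacency
effect that motivates k-mer features.  It emits a reference genome,
per-site methylation truth, signal-bearing aligned reads with move tables,
and a matched BS-seq cytosine report with binomial sampling noise.

Every generator is deterministic under a fixed seed; sub-streams are
derived with numpy's SeedSequence spawning so the reference, reads, and
BS-seq report are independent but reproducible.

The generative model is deliberately simple test scaffolding — per-base
signal is Gaussian around a per-context level, dwell counts are shifted
Poisson, alignment is exact by default.  It makes no claim of physical
pore realism (see docs/methods.md for what it does and does not emulate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .features import locate_motif_sites
from .types import AlignedSignalRead, ReferenceGenome, SiteTruth, revcomp

FrequencySpec = Union[float, Callable[[np.random.Generator], float]]
Mixture = Sequence[tuple[float, FrequencySpec]]

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    ``meth_level_shift`` (delta) and ``noise_sd`` (sigma) control
    separability: every signal sample whose context k-mer contains a
    methylated cytosine is shifted by delta, on top of Gaussian noise with
    standard deviation sigma around the context's table level.
    """

    genome_length: int = 50_000
    gc_fraction: float = 0.40
    read_length_mean: int = 1000
    depth: float = 20.0
    context_order: int = 6
    meth_level_shift: float = 1.5
    noise_sd: float = 1.0
    dwell_mean: float = 9.0
    bs_coverage: float = 50.0
    bs_conversion_error: float = 0.005
    sub_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for name in ("gc_fraction", "bs_conversion_error", "sub_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_length_mean <= 0 or self.depth <= 0:
            raise ValueError("read_length_mean and depth must be positive")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 (every base emits a sample)")
        if self.noise_sd < 0 or self.bs_coverage < 0:
            raise ValueError("noise_sd and bs_coverage must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass(frozen=True)
class TrueMethylation:
    """Ground-truth methylation frequency at one cytosine site."""

    chrom: str
    pos: int
    strand: str
    context_class: str
    trinucleotide: str
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


MethylationTruth = dict[tuple[str, int, str], TrueMethylation]


class KmerLevelTable:
    """Expected signal level per context k-mer, generated from a seed.

    Levels are iid Normal(0, scale) per k-mer; regeneration from the same
    seed is identical.  Lookup encodes the k-mer as a base-4 integer.

    The default scale equals the per-sample noise floor (1 signal unit):
    context effects perturb the signal at the same order as noise, while
    the methylation shifts of interest (1.5-3 units) dominate any single
    context's level, the regime a signal-level caller must operate in for
    contexts it has never seen in training.
    """

    def __init__(self, order: int, levels: np.ndarray):
        if len(levels) != 4 ** order:
            raise ValueError(f"need {4 ** order} levels for order {order}")
        self.order = order
        self.levels = np.asarray(levels, dtype=float)

    @classmethod
    def from_seed(cls, order: int, seed: int, scale: float = 1.0) -> "KmerLevelTable":
        rng = np.random.default_rng(np.random.SeedSequence((seed, 1000 + order)))
        return cls(order, rng.normal(0.0, scale, size=4 ** order))

    def encode(self, kmer: str) -> int:
        code = 0
        for b in kmer:
            code = code * 4 + _BASE_INDEX[b]
        return code

    def level(self, kmer: str) -> float:
        if len(kmer) != self.order:
            raise ValueError(f"k-mer {kmer!r} is not of order {self.order}")
        return float(self.levels[self.encode(kmer)])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_reference(config: SimConfig) -> ReferenceGenome:
    """A random single-chromosome reference with the configured GC content."""
    if config.genome_length < config.context_order:
        raise ValueError("genome shorter than the context window")
    rng = config.rng(0)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(rng.choice(_BASES, size=config.genome_length, p=probs))
    return ReferenceGenome({"chr1": seq})


def assign_truth_frequencies(ref: ReferenceGenome, motif_class: str,
                             mixture: Mixture, seed: int) -> MethylationTruth:
    """Draw a true methylation frequency for every motif site on both strands.

    ``mixture`` is a list of (weight, spec) components; a spec is either a
    fixed frequency (point mass) or a callable taking an rng and returning
    a frequency.  Point masses at 0 and 1 give the fully-unmethylated /
    fully-methylated populations used for training-site selection.
    """
    weights = np.array([w for w, _ in mixture], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture weights sum to {weights.sum()}, not 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    sites = locate_motif_sites(ref, motif_class)
    truth: MethylationTruth = {}
    for site in sites:
        component = rng.choice(len(mixture), p=weights)
        spec = mixture[component][1]
        freq = float(spec(rng)) if callable(spec) else float(spec)
        truth[site.key] = TrueMethylation(site.chrom, site.pos, site.strand,
                                          site.context_class, site.trinucleotide,
                                          min(max(freq, 0.0), 1.0))
    return truth


def simulate_reads(ref: ReferenceGenome, truth: MethylationTruth,
                   level_table: KmerLevelTable, config: SimConfig
                   ) -> list[AlignedSignalRead]:
    """Simulate signal-bearing aligned reads over the reference.

    Per read: a start, strand and length are sampled; each covered truth
    site becomes a Bernoulli(frequency) molecule state; each base emits
    ``1 + Poisson(dwell_mean - 1)`` Gaussian signal samples around its
    context level, shifted by ``meth_level_shift`` whenever the context
    k-mer contains a methylated cytosine.  Alignment is exact to the
    sampled origin unless ``sub_error_rate`` introduces substitutions.
    """
    if not ref.chroms:
        raise ValueError("empty reference")
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = config.rng(1)
    order = level_table.order
    left = (order - 1) // 2  # context bases upstream of the base itself
    delta = config.meth_level_shift
    sigma = config.noise_sd

    # truth sites grouped by strand for quick per-read slicing
    by_strand: dict[str, dict[tuple[str, int], float]] = {"+": {}, "-": {}}
    for t in truth.values():
        by_strand[t.strand][(t.chrom, t.pos)] = t.frequency

    reads: list[AlignedSignalRead] = []
    read_counter = 0
    for chrom, seq in ref.chroms.items():
        n = len(seq)
        n_reads = max(1, round(config.depth * n / config.read_length_mean))
        for _ in range(n_reads):
            length = int(np.clip(rng.normal(config.read_length_mean,
                                            0.1 * config.read_length_mean),
                                 2 * order, n))
            start = int(rng.integers(0, n - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            ref_segment = seq[start:start + length]
            read_seq = ref_segment if strand == "+" else revcomp(ref_segment)

            # substitution errors (optional; exercises the mismatch-skip rule)
            nm = 0
            if config.sub_error_rate > 0:
                chars = list(read_seq)
                for i in np.flatnonzero(rng.random(length) < config.sub_error_rate):
                    alternatives = [b for b in "ACGT" if b != chars[i]]
                    chars[i] = alternatives[rng.integers(0, 3)]
                    nm += 1
                read_seq = "".join(chars)

            # molecule methylation states in read coordinates
            meth_mask = np.zeros(length, dtype=bool)
            strand_truth = by_strand[strand]
            for offset in range(length):
                pos = start + offset
                freq = strand_truth.get((chrom, pos))
                if freq is not None and rng.random() < freq:
                    read_idx = offset if strand == "+" else length - 1 - offset
                    meth_mask[read_idx] = True

            # per-base shift: does the base's context k-mer contain a methylated C?
            # window of base i spans read positions [i-left, i-left+order);
            # conv[j] sums the mask over [j-order+1, j]
            conv = np.convolve(meth_mask.astype(int), np.ones(order, dtype=int))
            shifted = conv[np.arange(length) + order - 1 - left] > 0

            padded = "A" * left + read_seq + "A" * (order - 1 - left)
            dwells = 1 + rng.poisson(config.dwell_mean - 1.0, size=length)
            levels = np.array([level_table.level(padded[i:i + order])
                               for i in range(length)])
            levels = levels + delta * shifted
            total = int(dwells.sum())
            signal = rng.normal(np.repeat(levels, dwells), sigma, size=total)
            starts = np.concatenate([[0], np.cumsum(dwells)[:-1]])
            segments = list(zip(starts.tolist(), dwells.tolist()))

            quals = np.clip(np.rint(rng.normal(30.0, 3.0, size=length)), 2, 50).astype(int)
            read = AlignedSignalRead(
                read_id=f"sim_{read_counter:06d}", basecalled_seq=read_seq,
                qualities=quals, signal=signal, move_segments=segments,
                chrom=chrom, ref_start=start, strand=strand,
                cigar=f"{length}M", mapq=60, nm=nm)
            read.validate()
            reads.append(read)
            read_counter += 1
    return reads


def simulate_bsseq_report(truth: MethylationTruth, bs_coverage: float,
                          bs_conversion_error: float, seed: int) -> list[SiteTruth]:
    """Matched BS-seq counts: Poisson coverage, binomial methylated reads.

    Conversion error moves the effective methylation probability toward
    the opposite state symmetrically: p = f(1-e) + (1-f)e.  Sites drawing
    zero coverage are absent from the report.
    """
    if bs_coverage < 1:
        raise ValueError("bs_coverage must be >= 1")
    if not 0.0 <= bs_conversion_error <= 1.0:
        raise ValueError("bs_conversion_error must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    report: list[SiteTruth] = []
    for t in sorted(truth.values(), key=lambda s: (s.chrom, s.pos, s.strand)):
        total = int(rng.poisson(bs_coverage))
        if total == 0:
            continue
        p = t.frequency * (1 - bs_conversion_error) + (1 - t.frequency) * bs_conversion_error
        meth = int(rng.binomial(total, min(max(p, 0.0), 1.0)))
        report.append(SiteTruth(t.chrom, t.pos, t.strand, t.context_class,
                                t.trinucleotide, meth, total))
    return report


def simulate_dataset(config: SimConfig, motif_class: str, mixture: Mixture
                     ) -> tuple[ReferenceGenome, MethylationTruth,
                                list[AlignedSignalRead], list[SiteTruth]]:
    """Convenience wrapper: reference, truth, reads, and BS-seq report."""
    ref = generate_reference(config)
    truth = assign_truth_frequencies(ref, motif_class, mixture, seed=config.seed)
    table = KmerLevelTable.from_seed(config.context_order, config.seed)
    reads = simulate_reads(ref, truth, table, config)
    report = simulate_bsseq_report(truth, config.bs_coverage,
                                   config.bs_conversion_error, seed=config.seed)
    return ref, truth, reads, report
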