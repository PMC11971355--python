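"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the only
1-based surfaces are the Bismark-style cytosine report reader/writer.
Strand is ``"+"`` or ``"-"``; a minus-strand site refers to the cytosine on
the reverse-complement strand (a G on the forward reference sequence).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
CONTEXT_CLASSES = ("CpG", "CHG", "CHH")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class RecordInvariantError(ValueError):
    """A parsed or constructed record violates a type invariant."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise RecordInvariantError(f"unparseable CIGAR string: {cigar!r}")
    return ops


def cigar_read_length(cigar: str) -> int:
    """Number of read bases the CIGAR consumes (M/I/S/=/X)."""
    return sum(n for n, op in parse_cigar(cigar) if op in "MIS=X")


@dataclass
class ReferenceGenome:
    """An in-memory reference: chromosome name -> uppercase sequence."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        self.chroms = {name: seq.upper() for name, seq in self.chroms.items()}

    def __len__(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in self.chroms.items()]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        return cls({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")})


@dataclass
class AlignedSignalRead:
    """One basecalled read with raw signal, move table, and its alignment.

    ``basecalled_seq``, ``qualities``, ``signal`` and ``move_segments`` are
    all in the molecule's own 5'->3' (sequencing) orientation; ``cigar`` is
    in reference orientation, as in SAM.  ``move_segments[i]`` is the
    ``(start, length)`` span of base ``i`` within ``signal``.
    """

    read_id: str
    basecalled_seq: str
    qualities: np.ndarray
    signal: np.ndarray
    move_segments: list[tuple[int, int]]
    chrom: str
    ref_start: int
    strand: str
    cigar: str
    mapq: int
    nm: int = 0  # mismatch count within aligned columns

    def validate(self) -> None:
        n = len(self.basecalled_seq)
        if len(self.qualities) != n:
            raise RecordInvariantError(
                f"read {self.read_id}: {len(self.qualities)} qualities for {n} bases")
        if len(self.move_segments) != n:
            raise RecordInvariantError(
                f"read {self.read_id}: {len(self.move_segments)} move segments for {n} bases")
        expected_start = 0
        for i, (start, length) in enumerate(self.move_segments):
            if length < 1:
                raise RecordInvariantError(
                    f"read {self.read_id}: segment {i} has length {length} < 1")
            if start != expected_start:
                raise RecordInvariantError(
                    f"read {self.read_id}: segment {i} starts at {start}, expected {expected_start}")
            expected_start = start + length
        if expected_start != len(self.signal):
            raise RecordInvariantError(
                f"read {self.read_id}: move segments cover {expected_start} samples "
                f"but signal has {len(self.signal)}")
        if cigar_read_length(self.cigar) != n:
            raise RecordInvariantError(
                f"read {self.read_id}: CIGAR consumes {cigar_read_length(self.cigar)} "
                f"read bases but sequence has {n}")
        if self.strand not in "+-":
            raise RecordInvariantError(f"read {self.read_id}: bad strand {self.strand!r}")
        if not 0 <= self.mapq <= 60:
            raise RecordInvariantError(f"read {self.read_id}: MAPQ {self.mapq} outside 0..60")

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (read_index, ref_position) for aligned (M/=/X) columns.

        Read indices are in the molecule's sequencing orientation: for a
        minus-strand read the CIGAR walks the reverse-complemented read, so
        index ``j`` in reference orientation maps to ``len - 1 - j``.
        """
        n = len(self.basecalled_seq)
        rpos = 0  # read index in reference orientation
        gpos = self.ref_start
        for length, op in parse_cigar(self.cigar):
            if op in "M=X":
                for k in range(length):
                    j = rpos + k
                    i = j if self.strand == "+" else n - 1 - j
                    yield i, gpos + k
                rpos += length
                gpos += length
            elif op in "IS":
                rpos += length
            elif op in "DN":
                gpos += length
        # H and P consume nothing relevant here

    @property
    def aligned_fraction(self) -> float:
        clipped = sum(n for n, op in parse_cigar(self.cigar) if op in "SH")
        total = len(self.basecalled_seq)
        return (total - clipped) / total if total else 0.0

    @property
    def identity(self) -> float:
        aligned_cols = sum(n for n, op in parse_cigar(self.cigar) if op in "M=X")
        if aligned_cols == 0:
            return 0.0
        return (aligned_cols - self.nm) / aligned_cols


@dataclass(frozen=True)
class CytosineSite:
    """A cytosine position on a specific strand of the reference."""

    chrom: str
    pos: int  # 0-based position on the forward reference coordinate system
    strand: str
    context_class: str
    trinucleotide: str  # 5'->3' on the C-bearing strand; [0] is always C

    def __post_init__(self) -> None:
        if self.trinucleotide[0] != "C":
            raise RecordInvariantError(
                f"trinucleotide {self.trinucleotide!r} does not start with C")
        if self.context_class not in CONTEXT_CLASSES:
            raise RecordInvariantError(f"unknown context class {self.context_class!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass
class SiteTruth:
    """BS-seq truth at one cytosine site (counts from a cytosine report)."""

    chrom: str
    pos: int  # 0-based
    strand: str
    context_class: str
    trinucleotide: str
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.total_count < 0:
            raise RecordInvariantError("negative counts in cytosine report record")
        if self.meth_count > self.total_count:
            raise RecordInvariantError(
                f"site {self.chrom}:{self.pos}{self.strand}: methylated count "
                f"{self.meth_count} exceeds total {self.total_count}")

    @property
    def quantified(self) -> bool:
        return self.total_count > 0

    @property
    def frequency(self) -> Optional[float]:
        if self.total_count == 0:
            return None
        return self.meth_count / self.total_count

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass
class SiteCallRecord:
    """Aggregated nanopore methylation call at one site."""

    chrom: str
    pos: int  # 0-based
    strand: str
    context_class: str
    coverage: int
    meth_reads: int
    quantified: bool = True

    def __post_init__(self) -> None:
        if self.meth_reads > self.coverage:
            raise RecordInvariantError(
                f"site {self.chrom}:{self.pos}{self.strand}: methylated reads "
                f"{self.meth_reads} exceed coverage {self.coverage}")

    @property
    def frequency(self) -> float:
        return self.meth_reads / self.coverage if self.coverage else float("nan")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass
class ReadCall:
    """Per-read methylation probability at one site.

    ``p_meth`` is the classifier's methylation probability P_m; the
    non-methylation probability is its complement.
    """

    read_id: str
    chrom: str
    pos: int
    strand: str
    p_meth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_meth <= 1.0:
            raise RecordInvariantError(f"P_m {self.p_meth} outside [0, 1]")

    @property
    def p_unmeth(self) -> float:
        return 1.0 - self.p_meth

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass
class FeatureRecord:
    """Per-read, per-cytosine feature matrices for the classifier.

    ``seq_features`` is k x 5: per base (mean of sampled standardized
    signal, std of sampled standardized signal, basecall quality, number of
    raw signal samples, base code A=0 C=1 G=2 T=3).  ``signal_features`` is
    k x 15 sampled standardized signal values.
    """

    read_id: str
    chrom: str
    pos: int
    strand: str
    kmer: str
    seq_features: np.ndarray
    signal_features: np.ndarray
    label: Optional[int] = None

    def __post_init__(self) -> None:
        k = len(self.kmer)
        if k % 2 == 0:
            raise RecordInvariantError(f"k-mer length {k} must be odd")
        if self.kmer[(k - 1) // 2] != "C":
            raise RecordInvariantError(f"k-mer {self.kmer!r} center is not C")
        self.seq_features = np.asarray(self.seq_features, dtype=float)
        self.signal_features = np.asarray(self.signal_features, dtype=float)
        if self.seq_features.shape != (k, 5):
            raise RecordInvariantError(
                f"seq_features shape {self.seq_features.shape} != ({k}, 5)")
        if self.signal_features.shape != (k, 15):
            raise RecordInvariantError(
                f"signal_features shape {self.signal_features.shape} != ({k}, 15)")
        if self.label is not None and self.label not in (0, 1):
            raise RecordInvariantError(f"label {self.label!r} not in {{0, 1}}")

    @property
    def k(self) -> int:
        return len(self.kmer)
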