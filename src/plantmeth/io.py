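"""Readers and writers for every format the pipeline touches.

Formats
-------
* native signal-alignment dialect: a self-describing TSV that carries the
  basecalled sequence, qualities, move table and raw signal inline, so the
  whole pipeline runs from plain text;
* SAM with an ONT-style ``mv`` move-table tag (signal inline in a float
  array tag), as an adapter for real basecaller output, via pysam;
* Bismark-style cytosine reports (1-based positions on disk, 0-based in
  memory — this reader/writer pair is the only place that conversion
  happens, together with the site-call writer);
* feature TSV (six-decimal precision), per-read call TSV, and a
  bedMethyl-like per-site TSV (frequencies as percentages, one decimal).

Parsers validate each record and raise :class:`ParseError` with the file
and line of the offending record; nothing is silently dropped.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam

from .types import (
    AlignedSignalRead,
    FeatureRecord,
    ReadCall,
    RecordInvariantError,
    SiteCallRecord,
    SiteTruth,
    revcomp,
)

NATIVE_HEADER = "#plantmeth-signal-alignment-v1"
FEATURE_HEADER = "#plantmeth-features-v1"
FEATURE_DECIMALS = 6


class ParseError(ValueError):
    """A file record could not be parsed or violated an invariant."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# native signal-alignment dialect
# ---------------------------------------------------------------------------


def write_signal_alignments(reads: Iterable[AlignedSignalRead], path) -> None:
    """Write reads in the native tab-separated dialect (full float precision)."""
    with _open_text(path, "wt") as fh:
        fh.write(NATIVE_HEADER + "\n")
        for read in reads:
            read.validate()
            fields = [
                read.read_id, read.chrom, str(read.ref_start), read.strand,
                str(read.mapq), str(read.nm), read.cigar, read.basecalled_seq,
                ",".join(str(int(q)) for q in read.qualities),
                ",".join(str(length) for _, length in read.move_segments),
                ",".join(repr(float(v)) for v in read.signal),
            ]
            fh.write("\t".join(fields) + "\n")


def _segments_from_lengths(lengths: list[int]) -> list[tuple[int, int]]:
    segments = []
    start = 0
    for length in lengths:
        segments.append((start, length))
        start += length
    return segments


def parse_signal_alignments(path, dialect: str = "native") -> Iterator[AlignedSignalRead]:
    """Stream validated reads from a signal-alignment file.

    ``dialect`` is ``"native"`` (the package's TSV) or ``"sam"`` (SAM with a
    stride-annotated ``mv`` move tag and inline signal tag).
    """
    if dialect == "native":
        yield from _parse_native(path)
    elif dialect == "sam":
        yield from _parse_sam(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _parse_native(path) -> Iterator[AlignedSignalRead]:
    with _open_text(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != NATIVE_HEADER:
            raise ParseError(path, 1, f"missing dialect header {NATIVE_HEADER!r}")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise ParseError(path, line_no,
                                 f"expected 11 fields, found {len(fields)}")
            try:
                read = AlignedSignalRead(
                    read_id=fields[0], chrom=fields[1], ref_start=int(fields[2]),
                    strand=fields[3], mapq=int(fields[4]), nm=int(fields[5]),
                    cigar=fields[6], basecalled_seq=fields[7],
                    qualities=np.array([int(q) for q in fields[8].split(",")]),
                    move_segments=_segments_from_lengths(
                        [int(x) for x in fields[9].split(",")]),
                    signal=np.array([float(v) for v in fields[10].split(",")]),
                )
                read.validate()
            except (ValueError, RecordInvariantError) as exc:
                raise ParseError(path, line_no, str(exc)) from exc
            yield read


# ---------------------------------------------------------------------------
# SAM dialect (mv move tag + inline signal tag)
# ---------------------------------------------------------------------------


def write_signal_alignments_sam(reads: Iterable[AlignedSignalRead], path,
                                ref_lengths: Mapping[str, int]) -> None:
    """Write reads as SAM with ONT-style tags.

    Sequence and qualities follow SAM convention (reference orientation for
    minus-strand reads); the ``mv`` tag (stride 1, one flag per signal
    sample marking base starts) and the ``sg`` signal tag stay in
    sequencing orientation, as real basecallers emit them.
    """
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            read.validate()
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = read.read_id
            aln.flag = 16 if read.strand == "-" else 0
            aln.reference_name = read.chrom
            aln.reference_start = read.ref_start
            aln.mapping_quality = read.mapq
            aln.cigarstring = read.cigar
            if read.strand == "-":
                aln.query_sequence = revcomp(read.basecalled_seq)
                aln.query_qualities = list(read.qualities[::-1].astype(int))
            else:
                aln.query_sequence = read.basecalled_seq
                aln.query_qualities = list(np.asarray(read.qualities).astype(int))
            moves = np.zeros(len(read.signal), dtype=int)
            for start, _ in read.move_segments:
                moves[start] = 1
            aln.set_tag("mv", [1] + moves.tolist())  # stride, then per-sample flags
            aln.set_tag("sg", [float(v) for v in read.signal])
            aln.set_tag("NM", read.nm)
            out.write(aln)


def _parse_sam(path) -> Iterator[AlignedSignalRead]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if not aln.has_tag("mv"):
                raise RecordInvariantError(
                    f"read {aln.query_name}: no mv move-table tag; record unusable")
            if not aln.has_tag("sg"):
                raise RecordInvariantError(
                    f"read {aln.query_name}: no sg signal tag; record unusable")
            mv = list(aln.get_tag("mv"))
            stride, moves = int(mv[0]), np.asarray(mv[1:], dtype=int)
            signal = np.asarray(list(aln.get_tag("sg")), dtype=float)
            starts = np.flatnonzero(moves == 1) * stride
            if len(starts) == 0 or starts[0] != 0:
                raise RecordInvariantError(
                    f"read {aln.query_name}: move table does not start a base at sample 0")
            lengths = np.diff(np.append(starts, len(signal)))
            strand = "-" if aln.is_reverse else "+"
            seq = aln.query_sequence
            quals = np.asarray(aln.query_qualities, dtype=int)
            if strand == "-":
                seq = revcomp(seq)
                quals = quals[::-1]
            segments = list(zip(starts.tolist(), lengths.tolist()))
            if len(segments) != len(seq):
                raise RecordInvariantError(
                    f"read {aln.query_name}: move table defines {len(segments)} bases "
                    f"but sequence has {len(seq)}")
            read = AlignedSignalRead(
                read_id=aln.query_name, basecalled_seq=seq, qualities=quals,
                signal=signal, move_segments=segments,
                chrom=aln.reference_name, ref_start=aln.reference_start,
                strand=strand, cigar=aln.cigarstring, mapq=aln.mapping_quality,
                nm=int(aln.get_tag("NM")) if aln.has_tag("NM") else 0)
            read.validate()
            yield read


# ---------------------------------------------------------------------------
# cytosine reports (Bismark CX-like)
# ---------------------------------------------------------------------------


def write_cytosine_report(truth: Iterable[SiteTruth] | Mapping[tuple, SiteTruth],
                          path) -> None:
    """Write a CX-report-like TSV: chrom, 1-based pos, strand, methylated
    count, unmethylated count, context class, trinucleotide."""
    if isinstance(truth, Mapping):
        truth = truth.values()
    records = sorted(truth, key=lambda s: (s.chrom, s.pos, s.strand))
    with _open_text(path, "wt") as fh:
        for s in records:
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{s.meth_count}\t"
                     f"{s.total_count - s.meth_count}\t{s.context_class}\t"
                     f"{s.trinucleotide}\n")


def read_cytosine_report(path) -> dict[tuple[str, int, str], SiteTruth]:
    """Read a cytosine report into a (chrom, 0-based pos, strand) -> SiteTruth map.

    Zero-coverage records are retained (``quantified`` False)."""
    truth: dict[tuple[str, int, str], SiteTruth] = {}
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(path, line_no,
                                 f"expected 7 columns, found {len(fields)}")
            try:
                meth = int(fields[3])
                unmeth = int(fields[4])
                site = SiteTruth(
                    chrom=fields[0], pos=int(fields[1]) - 1, strand=fields[2],
                    context_class=fields[5], trinucleotide=fields[6],
                    meth_count=meth, total_count=meth + unmeth)
            except (ValueError, RecordInvariantError) as exc:
                raise ParseError(path, line_no, str(exc)) from exc
            truth[site.key] = site
    return truth


# ---------------------------------------------------------------------------
# feature files
# ---------------------------------------------------------------------------


def write_feature_file(records: Iterable[FeatureRecord], path) -> None:
    """Write feature records as TSV, numeric values at six decimals."""
    fmt = f"%.{FEATURE_DECIMALS}f"
    with _open_text(path, "wt") as fh:
        fh.write(FEATURE_HEADER + "\n")
        for rec in records:
            label = "." if rec.label is None else str(rec.label)
            seq_flat = ",".join(fmt % v for v in rec.seq_features.ravel())
            sig_flat = ",".join(fmt % v for v in rec.signal_features.ravel())
            fh.write(f"{rec.read_id}\t{rec.chrom}\t{rec.pos}\t{rec.strand}\t"
                     f"{rec.kmer}\t{label}\t{seq_flat}\t{sig_flat}\n")


def read_feature_file(path) -> list[FeatureRecord]:
    records: list[FeatureRecord] = []
    with _open_text(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != FEATURE_HEADER:
            raise ParseError(path, 1, f"missing header {FEATURE_HEADER!r}")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(path, line_no,
                                 f"expected 8 fields, found {len(fields)}")
            try:
                kmer = fields[4]
                k = len(kmer)
                seq_feat = np.array([float(v) for v in fields[6].split(",")]).reshape(k, 5)
                sig_feat = np.array([float(v) for v in fields[7].split(",")]).reshape(k, 15)
                rec = FeatureRecord(
                    read_id=fields[0], chrom=fields[1], pos=int(fields[2]),
                    strand=fields[3], kmer=kmer,
                    seq_features=seq_feat, signal_features=sig_feat,
                    label=None if fields[5] == "." else int(fields[5]))
            except (ValueError, RecordInvariantError) as exc:
                raise ParseError(path, line_no, str(exc)) from exc
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# per-read calls and per-site output
# ---------------------------------------------------------------------------


def write_read_calls(calls: Iterable[ReadCall], path) -> None:
    """Per-read call TSV: read_id, chrom, pos, strand, P_m, binary call."""
    from .model import classify_read  # local import: model depends on nothing here
    with _open_text(path, "wt") as fh:
        fh.write("#read_id\tchrom\tpos\tstrand\tp_meth\tcall\n")
        for call in calls:
            label = 1 if classify_read(call) == "methylated" else 0
            fh.write(f"{call.read_id}\t{call.chrom}\t{call.pos}\t{call.strand}\t"
                     f"{call.p_meth:.6f}\t{label}\n")


def read_read_calls(path) -> list[ReadCall]:
    calls: list[ReadCall] = []
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(path, line_no,
                                 f"expected 6 fields, found {len(fields)}")
            try:
                calls.append(ReadCall(read_id=fields[0], chrom=fields[1],
                                      pos=int(fields[2]), strand=fields[3],
                                      p_meth=float(fields[4])))
            except (ValueError, RecordInvariantError) as exc:
                raise ParseError(path, line_no, str(exc)) from exc
    return calls


def write_site_calls(calls: Iterable[SiteCallRecord], path) -> None:
    """bedMethyl-like per-site TSV, canonically sorted by (chrom, pos, strand).

    Columns: chrom, start (0-based), end, context class, coverage, strand,
    methylation frequency as a percentage with one decimal.
    """
    records = sorted(calls, key=lambda c: (c.chrom, c.pos, c.strand))
    with _open_text(path, "wt") as fh:
        for c in records:
            if c.coverage <= 0:
                raise RecordInvariantError(
                    f"site {c.chrom}:{c.pos}{c.strand}: cannot write zero-coverage record")
            fh.write(f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t{c.context_class}\t"
                     f"{c.coverage}\t{c.strand}\t{100.0 * c.frequency:.1f}\n")
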