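"""Motif site location, k-mer counting, alignment filters, signal
standardization, feature matrices, and training-site selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plantmeth as pm
from plantmeth.features import (CHH_POSITIVE_THRESHOLDS, classify_context,
                                sample_signal_values)
from plantmeth.types import AlignedSignalRead, ReferenceGenome, SiteTruth, revcomp


def brute_force_sites(seq: str, context_class: str):
    """Independent scanner: forward scan of the sequence and of its reverse
    complement, with minus-strand coordinates mapped back."""
    n = len(seq)
    found = set()
    for i in range(n - 2):
        if classify_context(seq[i:i + 3]) == context_class:
            found.add((i, "+", seq[i:i + 3]))
    rc = revcomp(seq)
    for i in range(n - 2):
        if classify_context(rc[i:i + 3]) == context_class:
            found.add((n - 1 - i, "-", rc[i:i + 3]))
    return found


class TestLocateMotifSites:
    def test_palindromic_cpg_on_acgt(self):
        sites = pm.locate_motif_sites(ReferenceGenome({"c": "ACGT"}), "CpG")
        assert {(s.pos, s.strand) for s in sites} == {(1, "+"), (2, "-")}

    def test_cctg_hand_enumeration(self):
        ref = ReferenceGenome({"c": "CCTG"})
        chh = pm.locate_motif_sites(ref, "CHH")
        chg = pm.locate_motif_sites(ref, "CHG")
        assert [(s.pos, s.strand, s.trinucleotide) for s in chh] == [(0, "+", "CCT")]
        assert sorted((s.pos, s.strand, s.trinucleotide) for s in chg) == \
            [(1, "+", "CTG"), (3, "-", "CAG")]

    @pytest.mark.parametrize("context_class", ["CpG", "CHG", "CHH"])
    def test_matches_brute_force_scanner_on_random_sequence(self, context_class):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        sites = pm.locate_motif_sites(ReferenceGenome({"c": seq}), context_class)
        assert {(s.pos, s.strand, s.trinucleotide) for s in sites} == \
            brute_force_sites(seq, context_class)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            pm.locate_motif_sites(ReferenceGenome({"c": "ACGT"}), "CNN")


class TestCountMotifKmers:
    def test_all_chh_9mers(self):
        assert pm.count_motif_kmers(9, "CHH") == 36_864

    def test_trivial_3mer_chh(self):
        assert pm.count_motif_kmers(3, "CHH") == 9

    @pytest.mark.parametrize("k,context_class", [(9, "CpG"), (5, "CHG"), (7, "CHH")])
    def test_matches_closed_form(self, k, context_class):
        per_class = {"CpG": 4, "CHG": 3, "CHH": 9}
        assert pm.count_motif_kmers(k, context_class) == \
            per_class[context_class] * 4 ** (k - 3)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            pm.count_motif_kmers(8, "CHH")


def _plain_read(length=100, mapq=60, cigar=None, nm=0):
    return AlignedSignalRead(
        read_id="r", basecalled_seq="A" * length,
        qualities=np.full(length, 30), signal=np.zeros(length),
        move_segments=[(i, 1) for i in range(length)],
        chrom="chr1", ref_start=0, strand="+",
        cigar=cigar or f"{length}M", mapq=mapq, nm=nm)


class TestFilterAlignment:
    def test_low_mapq_dropped(self):
        decision = pm.filter_alignment(_plain_read(mapq=19))
        assert (decision.keep, decision.reason) == (False, "mapq")

    def test_low_aligned_fraction_dropped(self):
        decision = pm.filter_alignment(_plain_read(cigar="79M21S"))
        assert (decision.keep, decision.reason) == (False, "aligned_fraction")

    def test_low_identity_dropped(self):
        decision = pm.filter_alignment(_plain_read(nm=25))
        assert (decision.keep, decision.reason) == (False, "identity")

    def test_good_alignment_kept(self):
        read = _plain_read(cigar="95M5S", nm=5)  # frac 0.95, identity ~0.947
        assert pm.filter_alignment(read).keep

    def test_boundary_values_kept(self):
        read = _plain_read(mapq=20, cigar="80M20S", nm=16)  # exactly at thresholds
        assert pm.filter_alignment(read).keep


class TestStandardizeSignal:
    def test_hand_computed_example(self):
        out = pm.standardize_signal(np.array([1, 2, 3, 4, 100]))
        np.testing.assert_allclose(out, [-2, -1, 0, 1, 97])

    def test_constant_signal_maps_to_zeros(self):
        np.testing.assert_array_equal(pm.standardize_signal(np.array([5, 5, 5])),
                                      [0.0, 0.0, 0.0])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=5, max_size=60))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_output_has_zero_median_unit_mad(self, values):
        x = np.asarray(values)
        if np.median(np.abs(x - np.median(x))) == 0:
            return
        out = pm.standardize_signal(x)
        assert np.median(out) == pytest.approx(0.0, abs=1e-9)
        assert np.median(np.abs(out - np.median(out))) == pytest.approx(1.0, rel=1e-9)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            pm.standardize_signal(np.array([]))


class TestSignalSampling:
    def test_twenty_samples_take_evenly_spaced_indices(self):
        values = np.arange(20.0)
        expected = values[(np.arange(15) * 20) // 15]
        np.testing.assert_array_equal(sample_signal_values(values), expected)

    def test_four_samples_repeat_cyclically(self):
        a, b, c, d = 1.0, 2.0, 3.0, 4.0
        out = sample_signal_values(np.array([a, b, c, d]))
        np.testing.assert_array_equal(
            out, [a, b, c, d, a, b, c, d, a, b, c, d, a, b, c])

    @given(st.integers(1, 100))
    @settings(deadline=None, derandomize=True)
    def test_always_fifteen_order_preserving_values(self, n):
        values = np.arange(float(n))
        out = sample_signal_values(values)
        assert len(out) == 15
        assert set(out) <= set(values)
        if n >= 15:  # strictly increasing when downsampling
            assert np.all(np.diff(out) > 0)


class TestExtractFeatures:
    def test_shapes_and_center_on_simulated_reads(self, chh_simulation, chh_sites):
        read = chh_simulation["reads"][0]
        records = pm.extract_features(read, chh_sites, k=13)
        assert records
        for rec in records:
            assert rec.seq_features.shape == (13, 5)
            assert rec.signal_features.shape == (13, 15)
            assert rec.kmer[6] == "C"

    def test_minus_strand_mirrors_plus_strand_construction(self):
        """A minus-strand read built as the reverse complement of a plus
        read (segments reversed) yields the same k-mer and per-base
        signal counts for the equivalent site."""
        seq = "TACACATAG"  # molecule 5'->3'; C at read index 4, context CAT
        rng = np.random.default_rng(0)
        dwells = rng.integers(3, 8, len(seq))
        signal = rng.normal(size=int(dwells.sum()))
        starts = np.concatenate([[0], np.cumsum(dwells)[:-1]])
        plus = AlignedSignalRead(
            "p", seq, np.full(len(seq), 30), signal,
            list(zip(starts.tolist(), dwells.tolist())),
            "chr1", 0, "+", f"{len(seq)}M", 60)
        # the same molecule read from the other strand: the reference now
        # carries revcomp(seq), and read index i maps to position len-1-i
        minus = AlignedSignalRead(
            "m", seq, np.full(len(seq), 30), signal,
            list(zip(starts.tolist(), dwells.tolist())),
            "chr1", 0, "-", f"{len(seq)}M", 60)
        site_plus = pm.CytosineSite("chr1", 4, "+", "CHH", seq[4:7])
        site_minus = pm.CytosineSite("chr1", len(seq) - 1 - 4, "-", "CHH", seq[4:7])
        rec_p = pm.extract_features(plus, [site_plus], k=5)
        rec_m = pm.extract_features(minus, [site_minus], k=5)
        assert len(rec_p) == len(rec_m) == 1
        assert rec_p[0].kmer == rec_m[0].kmer
        np.testing.assert_array_equal(rec_p[0].seq_features[:, 3],
                                      rec_m[0].seq_features[:, 3])
        np.testing.assert_allclose(rec_p[0].signal_features,
                                   rec_m[0].signal_features)

    def test_mean_std_match_brute_force_recomputation(self, chh_simulation, chh_sites):
        """Oracle: recompute per-base statistics from raw segments with
        plain Python and compare to the emitted matrices."""
        import statistics
        for read in chh_simulation["reads"][:5]:
            records = pm.extract_features(read, chh_sites, k=9)
            raw = list(map(float, read.signal))
            med = statistics.median(raw)
            mad = statistics.median([abs(v - med) for v in raw])
            std_signal = [(v - med) / mad for v in raw]
            n = len(read.basecalled_seq)
            for rec in records[:4]:
                # center read index from the (error-free, all-M) alignment
                center = (rec.pos - read.ref_start if read.strand == "+"
                          else read.ref_start + n - 1 - rec.pos)
                read_idx = center - 4  # window start for k=9
                for j in range(9):
                    start, length = read.move_segments[read_idx + j]
                    seg = std_signal[start:start + length]
                    sampled = [seg[(i * length) // 15] for i in range(15)] \
                        if length >= 15 else [seg[i % length] for i in range(15)]
                    mean = sum(sampled) / 15
                    var = sum((v - mean) ** 2 for v in sampled) / 15
                    assert rec.seq_features[j, 0] == pytest.approx(mean, abs=1e-6)
                    assert rec.seq_features[j, 1] == pytest.approx(var ** 0.5, abs=1e-6)
                    assert rec.seq_features[j, 3] == length

    def test_mismatched_center_base_is_skipped(self):
        read = _plain_read(length=11)  # all-A read: no C anywhere
        site = pm.CytosineSite("chr1", 5, "+", "CHH", "CAA")
        assert pm.extract_features(read, [site], k=5) == []

    def test_oversized_k_warns_and_returns_empty(self):
        read = _plain_read(length=11)
        with pytest.warns(UserWarning):
            assert pm.extract_features(read, [], k=13) == []


def _truth_site(trinuc, freq_num, freq_den, context="CHH", pos=10):
    return SiteTruth("chr1", pos, "+", context, trinuc,
                     meth_count=freq_num, total_count=freq_den)


class TestSelectReferenceSites:
    def test_caa_above_cutoff_is_positive(self):
        pos, neg = pm.select_reference_sites(
            [_truth_site("CAA", 96, 100)], "CHH", min_coverage=5)
        assert len(pos) == 1 and not neg

    def test_cca_uses_looser_cutoff(self):
        pos, _ = pm.select_reference_sites(
            [_truth_site("CCA", 86, 100)], "CHH", min_coverage=5)
        assert len(pos) == 1

    def test_low_coverage_site_excluded(self):
        pos, neg = pm.select_reference_sites(
            [_truth_site("CTA", 0, 4)], "CHH", min_coverage=5)
        assert not pos and not neg

    def test_chh_negative_requires_exact_zero(self):
        _, neg = pm.select_reference_sites(
            [_truth_site("CTA", 1, 100)], "CHH", min_coverage=5)
        assert not neg

    def test_cpg_thresholds(self):
        sites = [_truth_site("CGA", 100, 100, context="CpG", pos=1),
                 _truth_site("CGT", 1, 100, context="CpG", pos=2)]
        pos, neg = pm.select_reference_sites(sites, "CpG", min_coverage=5)
        assert len(pos) == 1 and len(neg) == 1

    def test_unknown_chh_motif_raises(self):
        bad = SiteTruth("chr1", 3, "+", "CHH", "CGG", 5, 10)  # not a CHH trinuc
        with pytest.raises(ValueError, match="threshold table"):
            pm.select_reference_sites([bad], "CHH")

    def test_motif_threshold_table_covers_all_nine_chh_trinucs(self):
        assert set(CHH_POSITIVE_THRESHOLDS) == \
            {f"C{a}{b}" for a in "ACT" for b in "ACT"}
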