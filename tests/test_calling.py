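"""Adaptive threshold selection, binary calling, site aggregation,
downsampling, correlation, metric oracles, and SMOTE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plantmeth as pm
from plantmeth.calling import N_BINS, ThresholdRangeError
from plantmeth.types import ReadCall, SiteCallRecord, SiteTruth


def _calls(pms, chrom="chr1", pos=0, strand="+"):
    return [ReadCall(f"r{i}", chrom, pos, strand, p) for i, p in enumerate(pms)]


class TestSelectThreshold:
    def test_exactly_seventy_bins(self):
        result = pm.select_threshold(np.linspace(0.21, 0.89, 200))
        assert len(result.bin_edges) == N_BINS == 70
        np.testing.assert_allclose(result.bin_edges,
                                   0.20 + 0.01 * np.arange(70))
        assert result.bin_proportions.sum() == pytest.approx(1.0)

    def test_unique_empty_bin_becomes_threshold(self):
        # occupy every bin except [0.55, 0.56): the unique minimum
        pms = [0.205 + 0.01 * j for j in range(70) if j != 35]
        result = pm.select_threshold(np.array(pms))
        assert result.p_th == pytest.approx(0.55)

    def test_uniform_occupancy_ties_break_low(self):
        pms = [0.205 + 0.01 * j for j in range(70)]
        assert pm.select_threshold(np.array(pms)).p_th == pytest.approx(0.20)

    def test_out_of_range_calls_are_excluded_from_denominator(self):
        pms = np.concatenate([np.zeros(500), np.ones(500), [0.305, 0.305]])
        result = pm.select_threshold(pms)
        assert result.bin_proportions.sum() == pytest.approx(1.0)
        assert result.bin_proportions[10] == pytest.approx(1.0)  # [0.30, 0.31)

    def test_no_in_range_call_instructs_fallback(self):
        with pytest.raises(ThresholdRangeError, match="0.5"):
            pm.select_threshold(np.array([0.05, 0.95, 1.0]))

    def test_valley_found_between_bimodal_modes(self):
        rng = np.random.default_rng(0)
        low = rng.beta(2, 10, 3000)   # mode near 0.1-0.2
        high = rng.beta(10, 2, 3000)  # mode near 0.8-0.9
        result = pm.select_threshold(np.concatenate([low, high]))
        assert 0.3 < result.p_th < 0.7

    def test_accepts_read_call_objects(self):
        result = pm.select_threshold(_calls([0.25, 0.45, 0.45]))
        assert result.p_th != 0.45


class TestCallMethylation:
    def test_threshold_is_inclusive(self):
        thr = pm.select_threshold(np.linspace(0.2, 0.89, 100))
        out = pm.call_methylation(np.array([thr.p_th, thr.p_th - 0.001]), thr)
        np.testing.assert_array_equal(out, [1, 0])

    def test_certain_calls_pass_any_threshold(self):
        out = pm.call_methylation(np.ones(5), 0.89)
        np.testing.assert_array_equal(out, 1)


class TestAggregate:
    def test_three_of_five_is_sixty_percent(self):
        calls = _calls([0.9, 0.9, 0.9, 0.1, 0.1], pos=7)
        sites = pm.aggregate_site_frequencies(calls, np.array([1, 1, 1, 0, 0]),
                                              min_coverage=5)
        assert len(sites) == 1
        assert sites[0].frequency == pytest.approx(0.6)
        assert sites[0].quantified

    def test_below_min_coverage_is_unquantified(self):
        calls = _calls([0.9] * 9, pos=3)
        sites = pm.aggregate_site_frequencies(calls, np.ones(9, dtype=int),
                                              min_coverage=10)
        assert not sites[0].quantified

    def test_strands_never_merge(self):
        calls = (_calls([0.9] * 3, pos=4, strand="+")
                 + _calls([0.1] * 3, pos=5, strand="-"))
        sites = pm.aggregate_site_frequencies(calls, np.array([1, 1, 1, 0, 0, 0]),
                                              min_coverage=1)
        assert [(s.pos, s.strand, s.frequency) for s in sites] == \
            [(4, "+", 1.0), (5, "-", 0.0)]


class TestDownsample:
    @pytest.fixture(scope="class")
    def deep_reads(self):
        cfg = pm.SimConfig(genome_length=3000, depth=40, read_length_mean=300,
                           meth_level_shift=0.0, seed=31)
        ref = pm.generate_reference(cfg)
        truth = pm.assign_truth_frequencies(ref, "CHH", [(1.0, 0.0)], seed=31)
        table = pm.KmerLevelTable.from_seed(cfg.context_order, cfg.seed)
        return pm.simulate_reads(ref, truth, table, cfg), 3000

    @staticmethod
    def realized_depth(reads, genome_length):
        return sum(r.aligned_fraction * len(r.basecalled_seq)
                   for r in reads) / genome_length

    def test_target_above_actual_returns_everything(self, deep_reads):
        reads, length = deep_reads
        assert pm.downsample_reads(reads, 100.0, length, seed=0) == list(reads)

    def test_realized_depth_near_target(self, deep_reads):
        reads, length = deep_reads
        subset = pm.downsample_reads(reads, 10.0, length, seed=1)
        assert self.realized_depth(subset, length) == pytest.approx(10.0, rel=0.05)

    def test_same_seed_same_subset(self, deep_reads):
        reads, length = deep_reads
        a = pm.downsample_reads(reads, 10.0, length, seed=2)
        b = pm.downsample_reads(reads, 10.0, length, seed=2)
        assert [r.read_id for r in a] == [r.read_id for r in b]

    def test_depth_monotone_in_target(self, deep_reads):
        reads, length = deep_reads
        depths = [self.realized_depth(
            pm.downsample_reads(reads, t, length, seed=3), length)
            for t in (5, 10, 15, 20, 25, 30)]
        assert all(b >= a for a, b in zip(depths, depths[1:]))

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            pm.downsample_reads([], 5.0, 1000, seed=0)


def _site_call(pos, freq_num, freq_den, strand="+"):
    return SiteCallRecord("chr1", pos, strand, "CHH", freq_den, freq_num)


def _site_truth(pos, meth, total, strand="+"):
    return SiteTruth("chr1", pos, strand, "CHH", "CAA", meth, total)


class TestPearson:
    def test_identical_vectors_give_unity(self):
        calls = [_site_call(i, i, 10) for i in range(5)]
        truth = [_site_truth(i, i, 10) for i in range(5)]
        r, n = pm.pearson_site_correlation(calls, truth, min_cov_each=5)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_matches_textbook_covariance_formula(self):
        x = np.array([0.0, 0.5, 1.0])
        y = np.array([0.1, 0.4, 0.9])
        calls = [_site_call(i, int(xi * 10), 10) for i, xi in enumerate(x)]
        truth = [_site_truth(i, int(yi * 10), 10) for i, yi in enumerate(y)]
        r, _ = pm.pearson_site_correlation(calls, truth, min_cov_each=5)
        oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_truth_is_undefined(self):
        calls = [_site_call(i, i, 10) for i in range(3)]
        truth = [_site_truth(i, 5, 10) for i in range(3)]
        with pytest.raises(ValueError, match="variance"):
            pm.pearson_site_correlation(calls, truth, min_cov_each=5)

    def test_low_coverage_sites_excluded(self):
        calls = [_site_call(0, 1, 2)] + [_site_call(i, i, 10) for i in range(1, 4)]
        truth = [_site_truth(i, i, 10) for i in range(4)]
        _, n = pm.pearson_site_correlation(calls, truth, min_cov_each=5)
        assert n == 3


def brute_force_auc(labels, scores):
    """Fraction of correctly ordered positive-negative pairs, ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_separation_maxes_everything(self):
        labels = [1] * 5 + [0] * 5
        probs = [0.9] * 5 + [0.1] * 5
        report = pm.single_molecule_metrics(labels, probs, replicates=1)
        assert report.f1 == report.accuracy == report.auc == report.ap == 1.0

    def test_confusion_matrix_arithmetic(self):
        # TP=8, FP=2, FN=2, TN=8 -> precision = recall = F1 = accuracy = 0.8
        labels = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        probs = [0.9] * 8 + [0.9] * 2 + [0.1] * 2 + [0.1] * 8
        report = pm.single_molecule_metrics(labels, probs, replicates=1)
        assert report.precision == pytest.approx(0.8)
        assert report.recall == pytest.approx(0.8)
        assert report.f1 == pytest.approx(0.8)
        assert report.accuracy == pytest.approx(0.8)
        assert (report.tp, report.fp, report.fn, report.tn) == (8, 2, 2, 8)

    def test_four_ordered_pairs_give_unit_auc(self):
        report = pm.single_molecule_metrics([1, 1, 0, 0], [0.9, 0.8, 0.4, 0.3],
                                            replicates=1)
        assert report.auc == 1.0

    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)),
                    min_size=4, max_size=50))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_auc_equals_pair_ordering_brute_force(self, pairs):
        labels = [y for y, _ in pairs]
        scores = [s for _, s in pairs]
        if len(set(labels)) < 2:
            return
        report = pm.single_molecule_metrics(labels, scores, replicates=1)
        assert report.auc == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            pm.single_molecule_metrics([1, 1, 1], [0.9, 0.8, 0.7], replicates=1)

    def test_replicate_subsampling_is_balanced_and_averaged(self):
        rng = np.random.default_rng(0)
        labels = np.concatenate([np.ones(50), np.zeros(200)])
        probs = np.where(labels == 1, rng.beta(8, 2, 250), rng.beta(2, 8, 250))
        report = pm.single_molecule_metrics(labels, probs, replicates=3, seed=1,
                                            n_per_class=40)
        assert 0.5 < report.auc <= 1.0


class TestSmote:
    def test_identical_points_yield_identical_synthetics(self):
        minority = np.ones((5, 3))
        out = pm.smote_oversample(minority, n_new=4, k_neighbors=2, seed=0)
        np.testing.assert_array_equal(out, np.ones((4, 3)))

    def test_two_points_synthesize_on_the_segment(self):
        minority = np.array([[0.0, 0.0], [1.0, 2.0]])
        out = pm.smote_oversample(minority, n_new=50, k_neighbors=1, seed=1)
        assert np.all(out[:, 0] >= 0) and np.all(out[:, 0] <= 1)
        assert np.all(out[:, 1] >= 0) and np.all(out[:, 1] <= 2)
        np.testing.assert_allclose(out[:, 1], 2 * out[:, 0], atol=1e-12)

    def test_zero_requested_returns_empty(self):
        minority = np.zeros((4, 2))
        assert pm.smote_oversample(minority, 0, k_neighbors=2).shape == (0, 2)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        minority = rng.normal(size=(20, 4))
        a = pm.smote_oversample(minority, 10, seed=9)
        b = pm.smote_oversample(minority, 10, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_too_small_minority_rejected(self):
        with pytest.raises(ValueError):
            pm.smote_oversample(np.zeros((1, 2)), 5)
        with pytest.raises(ValueError):
            pm.smote_oversample(np.zeros((3, 2)), 5, k_neighbors=3)
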