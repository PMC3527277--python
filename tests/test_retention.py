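"""Persistent/control-only/mitotic-only classification, decile
retention, and reads-in-peaks correlation."""

import numpy as np
import pytest

from mitoret.intervals import GenomicInterval, IntervalSet, ReadSet
from mitoret.peaks import Peak
from mitoret.retention import (
    classify_sites,
    decile_retention,
    reads_in_peaks_correlation,
)


def make_peaks(spans, pvals=None, n_reads=None, chrom="chr2L"):
    n = len(spans)
    pvals = pvals or [1e-8] * n
    n_reads = n_reads or [20] * n
    return [
        Peak(
            interval=GenomicInterval(chrom, s, e),
            summit=(s + e) // 2,
            height=10,
            n_reads=nr,
            fold=5.0,
            p_value=pv,
        )
        for (s, e), pv, nr in zip(spans, pvals, n_reads)
    ]


class TestClassifySites:
    def test_identical_sets_all_persistent(self):
        peaks = make_peaks([(0, 100), (500, 700), (1000, 1100)])
        res = classify_sites(peaks, make_peaks([(0, 100), (500, 700), (1000, 1100)]))
        assert len(res.persistent) == 3
        assert len(res.control_only) == 0
        assert len(res.mitotic_only) == 0

    def test_disjoint_sets(self):
        c = make_peaks([(0, 100), (500, 700)])
        m = make_peaks([(2000, 2100)])
        res = classify_sites(c, m)
        assert len(res.persistent) == 0
        assert len(res.control_only) == 2
        assert len(res.mitotic_only) == 1

    def test_partition_invariant(self, small_experiment):
        from mitoret.peaks import call_peaks, extend_and_pileup

        cfg, control, mitotic, _ = small_experiment
        g = sum(cfg.genome.values())
        pc = call_peaks(extend_and_pileup(control, 36, cfg.genome), control, g)
        pm = call_peaks(extend_and_pileup(mitotic, 36, cfg.genome), mitotic, g)
        res = classify_sites(pc, pm)
        assert len(res.persistent) + len(res.control_only) == len(pc)

    def test_multi_overlap_assigned_to_largest_intersection(self):
        c = make_peaks([(0, 100), (100, 300)])
        m = make_peaks([(80, 200)])  # 20 bp with first, 100 bp with second
        res = classify_sites(c, m)
        assert res.pairing == [(0, 0), (1, 0)] or (1, 0) in res.pairing
        # both control peaks overlap the mitotic peak, so both persistent
        assert len(res.persistent) == 2

    def test_overlapping_peaks_within_condition_rejected(self):
        c = make_peaks([(0, 100), (50, 150)])
        with pytest.raises(ValueError, match="overlap"):
            classify_sites(c, [])

    def test_end_to_end_truth_recovery(self, small_experiment):
        from mitoret.intervals import overlap_pairs
        from mitoret.peaks import call_peaks, empirical_fdr, extend_and_pileup
        from mitoret.simulate import truth_retained

        cfg, control, mitotic, truth = small_experiment
        g = sum(cfg.genome.values())
        pc = empirical_fdr(
            call_peaks(extend_and_pileup(control, 36, cfg.genome), control, g), None
        )
        pm = empirical_fdr(
            call_peaks(extend_and_pileup(mitotic, 36, cfg.genome), mitotic, g), None
        )
        res = classify_sites(pc, pm)
        retained = truth_retained(truth)
        pairs, _ = overlap_pairs(res.persistent, retained)
        tp = len({j for _, j in pairs})
        fp = len(res.persistent) - len({i for i, _ in pairs})
        fn = len(retained) - tp
        assert tp / (tp + fp + fn) >= 0.8  # small-n variant of the recovery bar


class TestDecileRetention:
    def test_top_decile_only(self):
        # 20 control peaks; mitotic = exactly the 2 best-ranked (by p)
        pvals = [10 ** (-20 + i) for i in range(20)]
        spans = [(i * 1000, i * 1000 + 200) for i in range(20)]
        c = make_peaks(spans, pvals=pvals)
        m = make_peaks(spans[:2], pvals=pvals[:2])
        out = decile_retention(c, m, metric="p_value")
        assert out == [100.0] + [0.0] * 9

    def test_identical_sets_uniform(self):
        spans = [(i * 1000, i * 1000 + 200) for i in range(20)]
        pvals = [10 ** (-20 + i) for i in range(20)]
        c = make_peaks(spans, pvals=pvals)
        m = make_peaks(spans, pvals=pvals)
        for metric in ("p_value", "n_reads", "height", "fold"):
            out = decile_retention(c, m, metric=metric)
            assert out == [10.0] * 10

    def test_remainder_spread_over_leading_bins(self):
        # 23 peaks -> decile sizes 3,3,3,2,...,2
        spans = [(i * 1000, i * 1000 + 200) for i in range(23)]
        pvals = [10 ** (-30 + i) for i in range(23)]
        c = make_peaks(spans, pvals=pvals)
        m = make_peaks(spans[:3], pvals=pvals[:3])  # exactly decile 1
        out = decile_retention(c, m, metric="p_value")
        assert out == [100.0] + [0.0] * 9

    def test_output_sums_to_100_when_all_paired(self, small_experiment):
        from mitoret.peaks import call_peaks, extend_and_pileup

        cfg, control, mitotic, _ = small_experiment
        g = sum(cfg.genome.values())
        pc = call_peaks(extend_and_pileup(control, 36, cfg.genome), control, g)
        pm = call_peaks(extend_and_pileup(mitotic, 36, cfg.genome), mitotic, g)
        for metric in ("p_value", "n_reads"):
            out = decile_retention(pc, pm, metric=metric)
            assert all(0 <= v <= 100 for v in out)
            assert sum(out) <= 100 + 1e-9

    def test_occupancy_biased_retention_favors_top_decile(self, small_experiment):
        from mitoret.peaks import call_peaks, extend_and_pileup

        cfg, control, mitotic, _ = small_experiment
        g = sum(cfg.genome.values())
        pc = call_peaks(extend_and_pileup(control, 36, cfg.genome), control, g)
        pm = call_peaks(extend_and_pileup(mitotic, 36, cfg.genome), mitotic, g)
        out = decile_retention(pc, pm, metric="n_reads")
        assert out[0] > out[9]

    def test_errors(self):
        c = make_peaks([(i * 1000, i * 1000 + 100) for i in range(20)])
        with pytest.raises(ValueError, match="metric"):
            decile_retention(c, c, metric="banana")
        with pytest.raises(ValueError, match="10 control"):
            decile_retention(c[:5], c[:5])
        m = make_peaks([(900_000, 900_100)])
        with pytest.raises(ValueError, match="partner"):
            decile_retention(c, m)


class TestReadsInPeaksCorrelation:
    def _reads(self, counts, spans, chrom="chr2L"):
        reads = []
        for (s, _e), k in zip(spans, counts):
            reads += [(chrom, s + 10 + i % 50, "+") for i in range(k)]
        return ReadSet(reads=reads, total_mapped=max(1, len(reads)))

    def test_self_correlation_is_one(self):
        spans = [(i * 1000, i * 1000 + 200) for i in range(5)]
        union = IntervalSet([GenomicInterval("chr2L", s, e) for s, e in spans])
        a = self._reads([5, 10, 20, 3, 8], spans)
        assert reads_in_peaks_correlation(union, a, a) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        spans = [(0, 200), (1000, 1200), (2000, 2200)]
        union = IntervalSet([GenomicInterval("chr2L", s, e) for s, e in spans])
        a = self._reads([1, 2, 3], spans)
        b = self._reads([3, 2, 1], spans)
        assert reads_in_peaks_correlation(union, a, b) == pytest.approx(-1.0)

    def test_symmetric_in_read_sets(self):
        spans = [(i * 1000, i * 1000 + 200) for i in range(10)]
        union = IntervalSet([GenomicInterval("chr2L", s, e) for s, e in spans])
        rng = np.random.default_rng(0)
        a = self._reads(list(rng.integers(1, 30, 10)), spans)
        b = self._reads(list(rng.integers(1, 30, 10)), spans)
        assert reads_in_peaks_correlation(union, a, b) == pytest.approx(
            reads_in_peaks_correlation(union, b, a)
        )

    def test_recovers_known_correlation(self):
        # bivariate Poisson via a shared component: corr = s / sqrt((s+u)^2)
        rng = np.random.default_rng(42)
        n = 500
        shared = rng.poisson(40, n)
        a_counts = shared + rng.poisson(10, n)
        b_counts = shared + rng.poisson(10, n)
        true_r = 40 / 50  # shared variance fraction
        spans = [(i * 1000, i * 1000 + 200) for i in range(n)]
        union = IntervalSet([GenomicInterval("chr2L", s, e) for s, e in spans])
        a = self._reads(list(a_counts), spans)
        b = self._reads(list(b_counts), spans)
        r = reads_in_peaks_correlation(union, a, b)
        assert r == pytest.approx(true_r, abs=0.08)

    def test_degenerate_inputs_rejected(self):
        spans = [(0, 200), (1000, 1200)]
        union = IntervalSet([GenomicInterval("chr2L", s, e) for s, e in spans])
        flat = self._reads([5, 5], spans)
        varied = self._reads([2, 9], spans)
        with pytest.raises(ValueError, match="variance"):
            reads_in_peaks_correlation(union, flat, varied)
        with pytest.raises(ValueError, match="two peaks"):
            reads_in_peaks_correlation(IntervalSet([union[0]]), varied, varied)
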