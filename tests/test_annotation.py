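"""TSS assignment, border overlap summaries, and chromosome-scale
distributions."""

import numpy as np
import pytest

from mitoret.annotation import (
    border_overlap_summary,
    chromosome_distribution,
    genes_near_peaks,
    summarize_overlap,
    windowed_site_difference,
)
from mitoret.intervals import GenomicInterval, IntervalSet
from mitoret.io import TssRecord

from conftest import brute_force_overlap_pairs, random_interval_set


class TestGenesNearPeaks:
    def test_peak_covering_tss_distance_zero(self):
        peaks = IntervalSet([GenomicInterval("chr2L", 900, 1200)])
        tss = [TssRecord("g1", "chr2L", 1000)]
        out = genes_near_peaks(peaks, tss)
        assert out == {"g1": 0}

    def test_boundary_at_exactly_2kb(self):
        # peak ending 2001 bp upstream: nearest peak base is 2001 away
        peaks = IntervalSet([GenomicInterval("chr2L", 6900, 6999)])
        tss_out = [TssRecord("far", "chr2L", 8999)]
        tss_in = [TssRecord("near", "chr2L", 8998)]
        assert genes_near_peaks(peaks, tss_out, max_dist=2000) == {}
        assert genes_near_peaks(peaks, tss_in, max_dist=2000) == {"near": 2000}

    def test_planted_genes_recovered_exactly(self, rng):
        genome = {"chr2L": 10_000_000}
        tss = [
            TssRecord(f"g{i}", "chr2L", int(p))
            for i, p in enumerate(rng.integers(100_000, 9_900_000, 50))
        ]
        chosen = rng.choice(50, size=20, replace=False)
        peaks = IntervalSet(
            [
                GenomicInterval(
                    "chr2L",
                    tss[i].position + int(rng.integers(-1800, 1600)),
                    tss[i].position + int(rng.integers(1601, 2000)),
                )
                for i in chosen
            ]
        )
        out = genes_near_peaks(peaks, tss, max_dist=2000)
        expected = set()
        for rec in tss:
            for iv in peaks:
                d = max(0, max(iv.start - rec.position, rec.position - (iv.end - 1)))
                if d <= 2000:
                    expected.add(rec.gene_id)
        assert set(out) == expected
        assert {f"g{i}" for i in chosen} <= expected

    def test_monotone_in_max_dist(self, rng):
        genome = {"chr2L": 1_000_000}
        peaks = random_interval_set(rng, 30, genome, max_width=500)
        tss = [
            TssRecord(f"g{i}", "chr2L", int(p))
            for i, p in enumerate(rng.integers(0, 1_000_000, 100))
        ]
        prev = set()
        for d in (100, 1000, 5000, 50_000):
            cur = set(genes_near_peaks(peaks, tss, max_dist=d))
            assert prev <= cur
            prev = cur

    def test_empty_tss_rejected(self):
        peaks = IntervalSet([GenomicInterval("chr2L", 0, 10)])
        with pytest.raises(ValueError, match="empty TSS"):
            genes_near_peaks(peaks, [])


class TestBorderOverlap:
    def test_all_identical_full_fractions(self):
        s = IntervalSet([GenomicInterval("chr2L", i * 1000, i * 1000 + 100) for i in range(5)])
        res = border_overlap_summary(s, s, s)
        assert res.control.query_fraction == 1.0
        assert res.mitotic.query_fraction == 1.0
        assert res.borders_bound_control == 1.0
        assert res.preferential_retention_ratio == pytest.approx(1.0)

    def test_disjoint_borders_zero_fractions(self):
        peaks = IntervalSet([GenomicInterval("chr2L", 0, 100)])
        borders = IntervalSet([GenomicInterval("chr2L", 5000, 6000)])
        res = border_overlap_summary(peaks, peaks, borders)
        assert res.control.query_fraction == 0.0
        assert res.borders_bound_mitotic == 0.0

    def test_empty_border_set_rejected(self):
        peaks = IntervalSet([GenomicInterval("chr2L", 0, 100)])
        with pytest.raises(ValueError, match="border"):
            border_overlap_summary(peaks, peaks, IntervalSet([]))

    def test_fractions_match_brute_force(self, rng, toy_genome):
        for _ in range(10):
            q = random_interval_set(rng, 200, toy_genome)
            s = random_interval_set(rng, 200, toy_genome)
            summ = summarize_overlap(q, s)
            oracle = brute_force_overlap_pairs(q, s)
            assert summ.n_query_overlapping == len({i for i, _ in oracle})
            assert summ.n_subject_overlapped == len({j for _, j in oracle})

    def test_border_enriched_retention_recovered(self):
        """Retention biased 2x toward border sites shows up as a
        preferential-retention ratio near 2 (saturation-adjusted)."""
        from mitoret.simulate import (
            SimulationConfig,
            simulate_experiment,
            truth_borders,
            truth_retained,
            truth_sites,
        )

        ratios = []
        for seed in range(4):
            cfg = SimulationConfig(
                n_sites=1000,
                depth=10_000,
                retained_fraction=0.3,
                retained_bias=0.0,  # isolate the border effect
                border_retention_enrichment=2.0,
                seed=seed,
            )
            _, _, truth = simulate_experiment(cfg)
            res = border_overlap_summary(
                truth_sites(truth), truth_retained(truth), truth_borders(truth)
            )
            ratios.append(res.preferential_retention_ratio)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.2)


class TestChromosomeDistribution:
    def _sets(self):
        c = IntervalSet(
            [GenomicInterval("chr2L", i * 1000, i * 1000 + 100) for i in range(6)]
            + [GenomicInterval("chr4", i * 1000, i * 1000 + 100) for i in range(4)]
        )
        return c

    def test_identical_sets_zero_difference(self):
        c = self._sets()
        dist = chromosome_distribution(c, c)
        assert all(d == 0 for _, (_, _, d) in dist.items())
        assert sum(pc for _, (pc, _, _) in dist.items()) == pytest.approx(100)

    def test_chr4_loss(self):
        c = self._sets()
        m = c.filter_chromosomes(["chr4"])
        dist = chromosome_distribution(c, m)
        assert dist["chr4"][1] == 0.0
        assert dist["chr4"][2] == pytest.approx(40.0)
        assert dist["chr2L"][1] == pytest.approx(100.0)

    def test_uniform_thinning_within_sampling_error(self, rng, toy_genome):
        c = random_interval_set(rng, 2000, toy_genome)
        keep = rng.random(2000) < 0.3
        m = IntervalSet([iv for iv, k in zip(c, keep) if k])
        dist = chromosome_distribution(c, m)
        for chrom, (pc, pm, d) in dist.items():
            n_m = sum(1 for iv in m if iv.chrom == chrom)
            se = 100 * np.sqrt(max(pc / 100 * (1 - pc / 100) / len(m), 1e-12))
            assert abs(d) < 4 * se + 1e-9


class TestWindowedDifference:
    def test_identical_sets_all_zero(self, toy_genome):
        c = IntervalSet(
            [GenomicInterval("chr2L", i * 9000, i * 9000 + 100) for i in range(50)]
        )
        out = windowed_site_difference(c, c, toy_genome, window=100_000)
        assert all(d == 0 for *_, d in out)

    def test_deltas_sum_to_zero(self, rng, toy_genome):
        a = random_interval_set(rng, 300, toy_genome)
        b = random_interval_set(rng, 200, toy_genome)
        out = windowed_site_difference(a, b, toy_genome, window=250_000)
        assert sum(d for *_, d in out) == pytest.approx(0, abs=1e-9)

    def test_concentrated_mitotic_set(self, toy_genome):
        # control uniform over 10 windows; mitotic all in one window
        c = IntervalSet(
            [GenomicInterval("chr2L", i * 100_000 + 50, i * 100_000 + 150) for i in range(10)]
        )
        m = IntervalSet([GenomicInterval("chr2L", 50, 150) for _ in range(1)])
        out = windowed_site_difference(c, m, {"chr2L": 1_000_000}, window=100_000)
        deltas = [d for *_, d in out]
        assert min(deltas) == pytest.approx(10 - 100)
        assert deltas[0] == min(deltas)

    def test_window_larger_than_chromosome_single_window(self, toy_genome):
        c = IntervalSet([GenomicInterval("chr2L", 0, 100)])
        out = windowed_site_difference(c, c, {"chr2L": 1_000_000}, window=5_000_000)
        assert len(out) == 1
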