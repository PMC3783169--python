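"""RPM quantities, metagene profiles, initiation rates, pause ratios."""

import numpy as np
import pytest

from loopshift.core import Gene, GenomicInterval
from loopshift.io import CoverageTrack
from loopshift.signal import (
    ProfileConfig,
    compare_conditions,
    initiation_rate,
    metagene_profile,
    pause_ratio,
    region_rpm,
)


def track_from_positions(positions, strand="+", lib=None, chrom="chr1"):
    return CoverageTrack.from_positions(
        "t", strand, {chrom: np.asarray(positions, dtype=np.int64)}, lib
    )


def flat_track(start, end, count_per_bp, lib, strand="+", chrom="chr1"):
    runs = {
        chrom: (
            np.array([start]),
            np.array([end]),
            np.array([count_per_bp]),
        )
    }
    return CoverageTrack("t", strand, runs, lib)


def empty_track(strand="+", lib=1_000_000):
    return CoverageTrack("t", strand, {}, lib)


class TestRegionRpm:
    def test_basic_scaling(self):
        t = track_from_positions([100] * 50, lib=1_000_000)
        assert region_rpm(t, GenomicInterval("chr1", 0, 200)) == 50.0

    def test_empty_region_and_absent_chromosome(self):
        t = track_from_positions([100], lib=1_000_000)
        assert region_rpm(t, GenomicInterval("chr1", 500, 600)) == 0.0
        assert region_rpm(t, GenomicInterval("chr9", 0, 600)) == 0.0

    def test_zero_library_errors(self):
        t = CoverageTrack("t", "+", {}, 0)
        with pytest.raises(ValueError):
            region_rpm(t, GenomicInterval("chr1", 0, 10))

    def test_linearity_over_disjoint_regions(self):
        rng = np.random.default_rng(12)
        t = track_from_positions(rng.integers(0, 10_000, 500), lib=2_000_000)
        a = GenomicInterval("chr1", 0, 4_000)
        b = GenomicInterval("chr1", 4_000, 10_000)
        whole = GenomicInterval("chr1", 0, 10_000)
        assert region_rpm(t, a) + region_rpm(t, b) == pytest.approx(region_rpm(t, whole))

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(3)
        pos = rng.integers(0, 5_000, 400)
        t = track_from_positions(pos, lib=1_000_000)
        for s, e in [(0, 5_000), (100, 230), (4_990, 5_000)]:
            dense = np.bincount(pos, minlength=5_000)[s:e].sum()
            assert region_rpm(t, GenomicInterval("chr1", s, e)) == dense * 1e6 / 1_000_000


class TestMetagene:
    CFG = ProfileConfig(flank=500, min_gene_length=2_000)

    def test_flat_coverage_gives_flat_profile(self):
        lib = 1_000_000
        c = 3
        t = flat_track(0, 200_000, c, lib)
        genes = [
            Gene("a", "chr1", "+", 20_000, 40_000),
            Gene("b", "chr1", "-", 60_000, 100_000),
        ]
        prof = metagene_profile(genes, t, self.CFG)
        level = c * 1e6 / lib
        assert np.allclose(prof.promoter, level, rtol=1e-6)
        assert np.allclose(prof.body, level, rtol=1e-6)
        assert np.allclose(prof.tes, level, rtol=1e-6)
        assert prof.n_genes == 2

    def test_zero_coverage_gives_zero_profile(self):
        prof = metagene_profile(
            [Gene("a", "chr1", "+", 20_000, 40_000)], empty_track(), self.CFG
        )
        assert not prof.promoter.any() and not prof.body.any() and not prof.tes.any()

    def test_linear_ramp_body_reproduces_bin_means(self):
        # coverage value i at body base i: spline is exact on linear data
        gene = Gene("a", "chr1", "+", 10_000, 22_000)
        body_start, body_end = 10_500, 21_500  # flank 500
        n = body_end - body_start
        runs = {
            "chr1": (
                np.arange(body_start, body_end),
                np.arange(body_start, body_end) + 1,
                np.arange(n),
            )
        }
        lib = 1_000_000
        t = CoverageTrack("t", "+", runs, lib)
        prof = metagene_profile([gene], t, self.CFG)
        # closed-form bin means of f(x)=x sampled at 1000 points in [0, n-1]
        pts = np.linspace(0, n - 1, 1000)
        expected = pts.reshape(100, 10).mean(axis=1) * 1e6 / lib
        assert np.allclose(prof.body, expected, rtol=0.01)

    def test_short_genes_skipped_and_counted(self):
        genes = [
            Gene("long", "chr1", "+", 10_000, 40_000),
            Gene("short", "chr1", "+", 50_000, 52_500),  # body 1500 < 2000
        ]
        prof = metagene_profile(genes, empty_track(), self.CFG)
        assert prof.n_genes == 1 and prof.n_skipped_short == 1

    def test_no_eligible_gene_errors(self):
        with pytest.raises(ValueError):
            metagene_profile(
                [Gene("s", "chr1", "+", 0, 2_500)], empty_track(), self.CFG
            )

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        t = track_from_positions(rng.integers(0, 60_000, 2_000), lib=2_000_000)
        genes = [Gene("a", "chr1", "+", 10_000, 40_000)]
        p1 = metagene_profile(genes, t, self.CFG)
        p2 = metagene_profile(genes, t.scaled(2), self.CFG)
        assert np.allclose(p1.promoter, p2.promoter)
        assert np.allclose(p1.body, p2.body)


class TestInitiationRate:
    def test_sense_reads_counted(self):
        gene = Gene("g", "chr1", "+", 10_000, 30_000)
        plus = track_from_positions([10_000 - 250] * 30, "+", lib=1_000_000)
        minus = empty_track("-")
        sense, anti = initiation_rate(gene, plus, minus)
        assert sense == 30.0 and anti == 0.0

    def test_minus_strand_mirrors_plus(self):
        G = 100_000
        plus_reads = [40_100, 40_250, 39_800]
        anti_reads = [40_010]
        gene_p = Gene("g", "chr1", "+", 40_000, 60_000)
        plus = track_from_positions(plus_reads, "+", lib=1_000)
        minus = track_from_positions(anti_reads, "-", lib=1_000)
        s_p, a_p = initiation_rate(gene_p, plus, minus)
        # mirrored genome: position p -> G-1-p, strands swap
        gene_m = Gene("g", "chr1", "-", G - 60_000, G - 40_000)
        m_plus = track_from_positions([G - 1 - p for p in anti_reads], "+", lib=1_000)
        m_minus = track_from_positions([G - 1 - p for p in plus_reads], "-", lib=1_000)
        s_m, a_m = initiation_rate(gene_m, m_plus, m_minus)
        assert (s_m, a_m) == (s_p, a_p)


class TestPauseRatio:
    def test_exact_arithmetic_density_ratio(self):
        # 60 reads in the 600 bp window (0.1/bp) vs 197 in a 19700 bp body
        # (0.01/bp): density ratio exactly 10
        gene = Gene("g", "chr1", "+", 10_000, 30_000)
        tss_reads = list(np.linspace(9_700, 10_299, 60).astype(int))
        body_reads = list(np.linspace(10_300, 29_999, 197).astype(int))
        plus = track_from_positions(tss_reads + body_reads, "+", lib=1_000_000)
        ps = pause_ratio(gene, plus, empty_track("-"), pseudocount_reads=0)
        assert ps.pause_ratio == pytest.approx(10.0)

    def test_zero_body_undefined_without_pseudocount(self):
        gene = Gene("g", "chr1", "+", 10_000, 30_000)
        plus = track_from_positions([10_000] * 5, "+", lib=1_000)
        ps = pause_ratio(gene, plus, empty_track("-"), pseudocount_reads=0)
        assert ps.pause_ratio is None

    def test_pseudocount_keeps_ratio_defined(self):
        gene = Gene("g", "chr1", "+", 10_000, 30_000)
        plus = track_from_positions([10_000] * 5, "+", lib=1_000)
        ps = pause_ratio(gene, plus, empty_track("-"))
        assert ps.pause_ratio is not None and ps.pause_ratio > 1

    def test_short_gene_skipped(self):
        gene = Gene("g", "chr1", "+", 10_000, 10_500)  # body 200 < 300
        assert pause_ratio(gene, empty_track(), empty_track("-")) is None

    def test_monotone_in_window_and_body_counts(self):
        gene = Gene("g", "chr1", "+", 10_000, 30_000)
        minus = empty_track("-")

        def ratio(n_tss, n_body):
            reads = [10_050] * n_tss + [20_000] * n_body
            return pause_ratio(
                gene, track_from_positions(reads, "+", lib=1_000), minus
            ).pause_ratio

        assert ratio(20, 10) > ratio(10, 10) > ratio(10, 20)

    def test_strand_flip_consistency(self):
        """Mirroring the genome and swapping strands leaves metrics unchanged."""
        G = 200_000
        rng = np.random.default_rng(42)
        gene = Gene("g", "chr1", "+", 50_000, 90_000)
        sense = rng.integers(49_700, 90_000, 300)
        anti = rng.integers(49_700, 50_300, 40)
        plus = track_from_positions(sense, "+", lib=10_000)
        minus = track_from_positions(anti, "-", lib=10_000)
        ps = pause_ratio(gene, plus, minus, pseudocount_reads=0)
        gene_m = Gene("g", "chr1", "-", G - 90_000, G - 50_000)
        m_plus = track_from_positions(G - 1 - anti, "+", lib=10_000)
        m_minus = track_from_positions(G - 1 - sense, "-", lib=10_000)
        ps_m = pause_ratio(gene_m, m_plus, m_minus, pseudocount_reads=0)
        assert ps_m.tss_density == pytest.approx(ps.tss_density)
        assert ps_m.body_density == pytest.approx(ps.body_density)
        assert ps_m.pause_ratio == pytest.approx(ps.pause_ratio)
        assert ps_m.antisense_tss_rpm == pytest.approx(ps.antisense_tss_rpm)


class TestCompareConditions:
    def _stats(self, gene, reads, cond):
        plus = track_from_positions(reads, "+", lib=10_000)
        return pause_ratio(gene, plus, empty_track("-"), condition=cond)

    def test_identical_conditions(self):
        gene = Gene("g", "chr1", "+", 10_000, 30_000)
        genes = [Gene(f"g{i}", "chr1", "+", 10_000, 30_000) for i in range(5)]
        rng = np.random.default_rng(0)
        before = []
        for g in genes:
            reads = rng.integers(9_700, 30_000, 100)
            before.append(
                pause_ratio(g, track_from_positions(reads, "+", lib=10_000), empty_track("-"), condition="pre")
            )
        cmp = compare_conditions(before, before)
        assert cmp.test.statistic == 0 and cmp.test.p_value == 1

    def test_doubling_body_detected_as_increase(self):
        rng = np.random.default_rng(1)
        genes = [Gene(f"g{i}", "chr1", "+", 10_000, 30_000) for i in range(10)]
        before, after = [], []
        for g in genes:
            body = rng.integers(10_300, 30_000, 200)
            before.append(self._stats(g, body, "pre"))
            after.append(self._stats(g, np.concatenate([body, body]), "post"))
        cmp = compare_conditions(before, after, metric="body_density")
        assert cmp.direction == "increase"
        assert cmp.test.p_value < 1e-3 or cmp.test.degenerate

    def test_too_few_shared_genes(self):
        g = Gene("g", "chr1", "+", 10_000, 30_000)
        s = self._stats(g, [15_000] * 10, "pre")
        with pytest.raises(ValueError):
            compare_conditions([s], [s])
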