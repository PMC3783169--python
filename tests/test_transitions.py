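"""Transition classification, disruption inference, and the statistical tests."""

import numpy as np
import pytest
from scipy import stats

from loopshift.complexes import AnnotationConfig, GeneComplexAnnotation, assemble_complexes
from loopshift.core import Gene, GenomicInterval
from loopshift.io import InteractionPair
from loopshift.transitions import (
    TransitionRecord,
    chi_squared_table,
    classify_transitions,
    er_in_anchor_flag,
    filter_standalone_sites,
    group_mean_test,
    transition_contingency,
)


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def ann(gene_id, category, condition, complex_id="C0001", dist=0):
    return GeneComplexAnnotation(gene_id, condition, category, complex_id if category != "outside" else None, dist)


GENES = [
    Gene("ga", "chr1", "+", 10_000, 30_000),
    Gene("gb", "chr1", "+", 100_000, 130_000),
    Gene("gc", "chr1", "+", 200_000, 230_000),
    Gene("gd", "chr1", "+", 300_000, 330_000),
]
RESPONSE = {"ga": "induced", "gb": "repressed", "gc": "induced", "gd": "repressed"}


def classify(er_cats, standalone_sites):
    pre = [ann(g.gene_id, "anchor", "pre") for g in GENES]
    post = [
        ann(g.gene_id, c, "post") if c else ann(g.gene_id, "outside", "post")
        for g, c in zip(GENES, er_cats)
    ]
    return classify_transitions(GENES, RESPONSE, pre, post, standalone_sites)


class TestClassification:
    def test_four_categories_partition(self):
        # ga stays on an ER anchor; gb becomes a loop gene; gc has only a
        # stand-alone site 10 kb away; gd sees nothing.
        recs = classify(
            ["anchor", "loop", None, None],
            [iv(190_000, 190_400)],  # 10 kb upstream of gc's TSS
        )
        by_id = {r.gene_id: r for r in recs}
        assert by_id["ga"].transition == "anchor-to-anchor" and not by_id["ga"].disrupted
        assert by_id["gb"].transition == "anchor-to-loop" and by_id["gb"].disrupted
        assert by_id["gc"].transition == "anchor-to-stand-alone" and by_id["gc"].disrupted
        assert by_id["gd"].transition == "anchor-to-none" and by_id["gd"].disrupted
        assert len(recs) == len(GENES)  # exhaustive partition of anchor genes

    def test_non_anchor_genes_excluded(self):
        pre = [ann("ga", "anchor", "pre"), ann("gb", "loop", "pre")]
        post = [ann("ga", "anchor", "post"), ann("gb", "anchor", "post")]
        recs = classify_transitions(GENES[:2], RESPONSE, pre, post, [])
        assert [r.gene_id for r in recs] == ["ga"]

    def test_unknown_gene_errors(self):
        pre = [ann("missing", "anchor", "pre")]
        with pytest.raises(KeyError):
            classify_transitions(GENES, RESPONSE, pre, [], [])

    def test_filter_standalone_sites(self):
        cxs = assemble_complexes(
            [InteractionPair(iv(0, 1_000), iv(5_000, 6_000))]
        )
        sites = [iv(500, 700), iv(2_000, 2_300), iv(9_000, 9_100)]
        kept = filter_standalone_sites(sites, cxs)
        # only the site inside an anchor is removed; loop-region site stays
        assert kept == [iv(2_000, 2_300), iv(9_000, 9_100)]


class TestErInAnchor:
    def test_site_in_anchor_vs_loop_region(self):
        cx = assemble_complexes([InteractionPair(iv(0, 1_000), iv(5_000, 6_000))])[0]
        g = Gene("g", "chr1", "+", 500, 4_000)
        assert er_in_anchor_flag(g, cx, [iv(200, 300)])
        assert not er_in_anchor_flag(g, cx, [iv(2_000, 2_100)])  # loop DNA only


class TestContingency:
    def test_published_disruption_table_rejects_homogeneity(self):
        """86% (124/144) repressed vs 49% (104/213) induced disrupted."""
        res = chi_squared_table([[124, 20], [104, 109]])
        assert res.statistic == pytest.approx(51.7547, abs=1e-3)
        assert res.df == 1
        assert res.p_value < 1e-11

    def test_identity_margins_give_zero_statistic(self):
        res = chi_squared_table([[10, 10], [10, 10]])
        assert res.statistic == 0 and res.p_value == 1

    def test_row_and_column_swap_invariance(self):
        t = [[30, 11], [7, 25]]
        s0 = chi_squared_table(t).statistic
        assert chi_squared_table([t[1], t[0]]).statistic == pytest.approx(s0)
        assert chi_squared_table([r[::-1] for r in t]).statistic == pytest.approx(s0)

    def test_zero_expected_cell_errors(self):
        with pytest.raises(ValueError, match="expected"):
            chi_squared_table([[0, 5], [0, 7]])

    def test_from_records_collapsed_and_expanded(self):
        recs = []
        for cls, trans, n in [
            ("repressed", "anchor-to-anchor", 20),
            ("repressed", "anchor-to-loop", 124),
            ("induced", "anchor-to-anchor", 109),
            ("induced", "anchor-to-stand-alone", 104),
        ]:
            recs += [
                TransitionRecord(f"{cls}{trans}{i}", cls, "anchor", trans.split("-")[-1], trans, trans != "anchor-to-anchor")
                for i in range(n)
            ]
        res = transition_contingency(recs, collapse_to_disruption=True)
        assert res.table == ((104, 109), (124, 20))  # induced row first (sorted)
        assert res.p_value < 1e-11
        res3 = transition_contingency(recs, collapse_to_disruption=False)
        assert res3.df == 2

    def test_p_value_matches_monte_carlo_null(self):
        """Chi-squared tail probability agrees with a multinomial simulation."""
        table = np.array([[30, 20], [20, 30]])
        res = chi_squared_table(table)
        n = table.sum()
        probs = (
            np.outer(table.sum(axis=1), table.sum(axis=0)) / n**2
        ).ravel()
        rng = np.random.default_rng(0)
        draws = rng.multinomial(n, probs, size=20_000).reshape(-1, 2, 2)
        stats_null = []
        for t in draws:
            exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
            with np.errstate(divide="ignore", invalid="ignore"):
                s = np.nansum((t - exp) ** 2 / exp)
            stats_null.append(s)
        mc_p = np.mean(np.array(stats_null) >= res.statistic - 1e-12)
        se = np.sqrt(res.p_value * (1 - res.p_value) / 20_000)
        assert abs(mc_p - res.p_value) <= 3 * se + 1e-3


class TestGroupMeanTest:
    def test_identical_groups(self):
        r = group_mean_test([1, 2, 3], [1, 2, 3], paired=True)
        assert r.statistic == 0 and r.p_value == 1

    def test_constant_paired_shift_flagged(self):
        r = group_mean_test([2, 3, 4], [1, 2, 3], paired=True)
        assert r.p_value == 0 and r.degenerate

    def test_zero_variance_unpaired_equal_means(self):
        r = group_mean_test([5, 5, 5], [5, 5, 5])
        assert r.p_value == 1 and r.degenerate

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 2, 40)
        r = group_mean_test(a, b)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert r.statistic == pytest.approx(t) and r.p_value == pytest.approx(p)

    def test_power_on_unit_shift(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(200):
            a = rng.normal(0, 1, 100)
            b = rng.normal(1, 1, 100)
            if group_mean_test(a, b).p_value < 0.05:
                hits += 1
        assert hits / 200 >= 0.99

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            group_mean_test([1, 2], [1, 2, 3], paired=True)
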