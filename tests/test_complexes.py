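"""Complex assembly from interaction pairs and gene categorization."""

import networkx as nx
import numpy as np
import pytest

from loopshift.complexes import (
    AnnotationConfig,
    annotate_genes,
    assemble_complexes,
    assign_standalone,
    categorize_gene,
    complex_content,
)
from loopshift.core import Gene, GenomicInterval
from loopshift.io import InteractionPair
from .conftest import random_intervals


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def pair(a, b):
    return InteractionPair(a, b)


def bfs_components(pairs):
    """Oracle: connected components by pair membership or anchor overlap."""
    anchors = []
    g = nx.Graph()
    for p in pairs:
        i, j = len(anchors), len(anchors) + 1
        anchors += [p.anchor_a, p.anchor_b]
        g.add_edge(i, j)
    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            if anchors[i].overlaps(anchors[j]):
                g.add_edge(i, j)
    comps = []
    for comp in nx.connected_components(g):
        bases = set()
        for i in comp:
            bases |= {(anchors[i].chrom, b) for b in range(anchors[i].start, anchors[i].end)}
        comps.append(frozenset(bases))
    return set(comps)


class TestAssembly:
    def test_shared_anchor_chains_one_complex(self):
        pairs = [
            pair(iv(1_000, 2_000), iv(5_000, 6_000)),
            pair(iv(5_500, 6_500), iv(9_000, 10_000)),
        ]
        built = assemble_complexes(pairs)
        assert len(built) == 1
        cx = built[0]
        assert [a.start for a in cx.anchors] == [1_000, 5_000, 9_000]
        assert cx.anchors[1] == iv(5_000, 6_500)  # overlapping anchors merged
        assert (cx.span.start, cx.span.end) == (1_000, 10_000)
        assert cx.n_interactions == 2

    def test_separate_chromosomes_stay_separate(self):
        pairs = [
            pair(iv(0, 100), iv(500, 600)),
            pair(iv(0, 100, "chr2"), iv(500, 600, "chr2")),
        ]
        assert len(assemble_complexes(pairs)) == 2

    def test_inter_chromosomal_pairs_excluded(self):
        pairs = [pair(iv(0, 100), iv(500, 600, "chr2"))]
        assert assemble_complexes(pairs) == []

    def test_matches_bfs_oracle_on_random_pairs(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            ivs = random_intervals(rng, 40, 100_000, max_len=3_000)
            pairs = [
                pair(ivs[int(rng.integers(40))], ivs[int(rng.integers(40))])
                for _ in range(20)
            ]
            built = assemble_complexes(pairs)
            got = {
                frozenset(
                    (cx.chrom, b) for a in cx.anchors for b in range(a.start, a.end)
                )
                for cx in built
            }
            assert got == bfs_components(pairs)

    def test_deterministic_ids_by_position(self):
        pairs = [
            pair(iv(50_000, 51_000), iv(60_000, 61_000)),
            pair(iv(1_000, 2_000), iv(9_000, 10_000)),
        ]
        built = assemble_complexes(pairs)
        assert [c.complex_id for c in built] == ["C0001", "C0002"]
        assert built[0].span.start == 1_000


def make_complex():
    return assemble_complexes(
        [pair(iv(38_000, 42_000), iv(70_000, 72_000))]
    )


class TestCategorize:
    def test_tss_inside_anchor(self):
        g = Gene("g", "chr1", "+", 40_000, 60_000)
        ann = categorize_gene(g, make_complex())
        assert ann.category == "anchor" and ann.distance_to_nearest_anchor == 0

    def test_loop_gene_inside_span(self):
        g = Gene("g", "chr1", "+", 50_000, 65_000)
        ann = categorize_gene(g, make_complex())
        assert ann.category == "loop"
        assert ann.distance_to_nearest_anchor == 8_001  # 50000 - 41999

    def test_boundary_exactly_window_is_anchor(self):
        g = Gene("g", "chr1", "+", 47_000, 60_000)  # tss 47000, edge 41999 -> 5001
        assert categorize_gene(g, make_complex()).category == "loop"
        g2 = Gene("g2", "chr1", "+", 46_999, 60_000)  # distance exactly 5000
        assert categorize_gene(g2, make_complex()).category == "anchor"

    def test_outside_gene(self):
        g = Gene("g", "chr1", "+", 200_000, 220_000)
        ann = categorize_gene(g, make_complex())
        assert ann.category == "outside" and ann.complex_id is None

    def test_nearest_complex_wins_ties_by_id(self):
        cxs = assemble_complexes(
            [
                pair(iv(0, 1_000), iv(8_000, 9_000)),
                pair(iv(20_000, 21_000), iv(30_000, 31_000)),
            ]
        )
        g = Gene("g", "chr1", "+", 12_000, 40_000)  # 3001 bp to C0001, 8000 to C0002
        ann = categorize_gene(g, cxs)
        assert ann.category == "anchor" and ann.complex_id == "C0001"

    def test_window_monotonicity(self):
        g = Gene("g", "chr1", "+", 50_000, 65_000)
        cxs = make_complex()
        cats = [
            categorize_gene(g, cxs, AnnotationConfig(anchor_window=w)).category
            for w in (1_000, 5_000, 9_000)
        ]
        assert cats == ["loop", "loop", "anchor"]  # growing window only promotes

    def test_every_gene_gets_exactly_one_category(self):
        rng = np.random.default_rng(2)
        cxs = assemble_complexes(
            [pair(a, b) for a, b in zip(random_intervals(rng, 10, 200_000), random_intervals(rng, 10, 200_000))]
        )
        genes = [
            Gene(f"g{i}", "chr1", "+", int(s), int(s) + 5_000)
            for i, s in enumerate(rng.integers(0, 195_000, 50))
        ]
        anns = annotate_genes(genes, cxs)
        assert len(anns) == len(genes)
        assert all(a.category in ("anchor", "loop", "outside") for a in anns)


class TestStandalone:
    def test_distance_arithmetic(self):
        g = Gene("g", "chr1", "+", 90_000, 110_000)
        assert assign_standalone(g, [iv(75_000, 75_500)])  # 90000-75499 = 14501
        assert not assign_standalone(g, [iv(60_000, 60_100)])  # 29901 > 20000
        assert assign_standalone(g, [iv(89_000, 91_000)])  # overlapping TSS

    def test_boundary_inclusive(self):
        g = Gene("g", "chr1", "+", 90_000, 110_000)
        assert assign_standalone(g, [iv(69_000, 70_001)])  # distance exactly 20000


class TestComplexContent:
    def test_summary_counts(self):
        cxs = assemble_complexes(
            [
                pair(iv(0, 1_000), iv(5_000, 6_000)),
                pair(iv(50_000, 51_000), iv(55_000, 56_000)),
            ]
        )
        sites = {"er": [iv(100, 200), iv(400, 500), iv(5_100, 5_200)]}
        per_cx, summary = complex_content(cxs, sites, in_anchors_only=True)
        assert per_cx["C0001"]["er"] == 3 and per_cx["C0002"]["er"] == 0
        s = summary[0]
        assert s.n_with_site == 1 and s.fraction_with_site == 0.5
        assert s.mean_sites_among_positive == 3.0

    def test_empty_site_set(self):
        cxs = assemble_complexes([pair(iv(0, 1_000), iv(5_000, 6_000))])
        per_cx, summary = complex_content(cxs, {"er": []})
        assert per_cx["C0001"]["er"] == 0
        assert summary[0].n_with_site == 0 and summary[0].mean_sites_among_positive is None

    def test_matches_quadratic_scan(self):
        rng = np.random.default_rng(77)
        cxs = assemble_complexes(
            [
                pair(a, b)
                for a, b in zip(
                    random_intervals(rng, 8, 300_000, max_len=3_000),
                    random_intervals(rng, 8, 300_000, max_len=3_000),
                )
            ]
        )
        sites = random_intervals(rng, 60, 300_000)
        per_cx, _ = complex_content(cxs, {"f": sites}, in_anchors_only=True)
        for cx in cxs:
            expected = sum(
                1 for s in sites if any(s.overlaps(a) for a in cx.anchors)
            )
            assert per_cx[cx.complex_id]["f"] == expected
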