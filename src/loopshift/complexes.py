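"""Chromatin complex assembly and gene categorization.

A ChIA-PET experiment reports pairwise interactions between anchor
regions; a *chromatin complex* is a connected component of the graph whose
nodes are anchors and whose edges are (a) the interaction pairs and (b)
>=1 bp overlap between anchors. Genes are categorized against complexes:
an *anchor gene* has its TSS within ``anchor_window`` (default +/-5 kb,
boundary-inclusive) of an anchor region; a *loop gene* sits inside the
complex span but away from anchors; everything else is *outside*. A gene
with no complex can still be near a *stand-alone* binding site (default
window +/-20 kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    Gene,
    GenomicInterval,
    IntervalIndex,
    merge_intervals,
    point_to_interval_distance,
)
from .io import InteractionPair


@dataclass(frozen=True)
class AnnotationConfig:
    anchor_window: int = 5_000
    standalone_window: int = 20_000

    def __post_init__(self) -> None:
        if self.anchor_window <= 0 or self.standalone_window <= 0:
            raise ValueError("windows must be positive")


@dataclass
class ChromatinComplex:
    complex_id: str
    chrom: str
    anchors: list[GenomicInterval]
    n_interactions: int

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(a.start for a in self.anchors),
            max(a.end for a in self.anchors),
        )


@dataclass(frozen=True)
class GeneComplexAnnotation:
    gene_id: str
    condition: str
    category: str  # anchor | loop | outside
    complex_id: str | None
    distance_to_nearest_anchor: float


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def assemble_complexes(pairs: Sequence[InteractionPair]) -> list[ChromatinComplex]:
    """Group interaction pairs into complexes (connected components).

    Union-find over anchors: the two anchors of a pair are joined, and any
    two anchors overlapping by >=1 bp are joined. Anchors of a component
    are merged; complexes get deterministic ids ordered by (chrom, span
    start). Inter-chromosomal pairs are excluded.
    """
    intra = [p for p in pairs if not p.inter_chromosomal]
    anchors: list[GenomicInterval] = []
    pair_of: list[tuple[int, int]] = []
    for p in intra:
        anchors.append(p.anchor_a)
        anchors.append(p.anchor_b)
        pair_of.append((len(anchors) - 2, len(anchors) - 1))
    uf = _UnionFind(len(anchors))
    for i, j in pair_of:
        uf.union(i, j)
    # join overlapping anchors: sweep each chromosome; any anchor starting
    # inside the running merged region is transitively connected to it
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].chrom, anchors[i].start))
    run_chrom, run_end, run_rep = None, -1, -1
    for i in order:
        a = anchors[i]
        if a.chrom == run_chrom and a.start < run_end:
            uf.union(run_rep, i)
            run_end = max(run_end, a.end)
        else:
            run_chrom, run_end, run_rep = a.chrom, a.end, i
    comp_anchors: dict[int, list[int]] = {}
    for i in range(len(anchors)):
        comp_anchors.setdefault(uf.find(i), []).append(i)
    comp_pairs: dict[int, int] = {}
    for i, j in pair_of:
        comp_pairs[uf.find(i)] = comp_pairs.get(uf.find(i), 0) + 1
    built = []
    for root, members in comp_anchors.items():
        merged = merge_intervals([anchors[i] for i in members])
        built.append((merged[0].chrom, merged, comp_pairs.get(root, 0)))
    built.sort(key=lambda t: (t[0], t[1][0].start, t[1][-1].end))
    width = max(4, len(str(len(built))))
    return [
        ChromatinComplex(f"C{k:0{width}d}", chrom, merged, n_int)
        for k, (chrom, merged, n_int) in enumerate(built, start=1)
    ]


class ComplexIndex:
    """Query structure over a complex list: nearest anchor and covering span."""

    def __init__(self, complexes: Sequence[ChromatinComplex]):
        self.complexes = list(complexes)
        anchor_ivs = []
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for cx in self.complexes:
            for a in cx.anchors:
                anchor_ivs.append(a)
                by_chrom.setdefault(cx.chrom, []).append((a.start, a.end, cx.complex_id))
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in by_chrom.items():
            self._anchors[chrom] = (
                np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows], dtype=np.int64),
                np.array([r[2] for r in rows]),
            )
        self.anchor_index = IntervalIndex(anchor_ivs)
        self.span_index = IntervalIndex([cx.span for cx in self.complexes])

    def nearest_anchor(self, chrom: str, pos: int) -> tuple[float, str | None]:
        """(distance, complex_id) of the nearest anchor; ties -> smaller id."""
        if chrom not in self._anchors:
            return (float("inf"), None)
        starts, ends, cids = self._anchors[chrom]
        inside = (starts <= pos) & (pos < ends)
        d = np.minimum(np.abs(pos - starts), np.abs(pos - (ends - 1)))
        d = np.where(inside, 0, d)
        dmin = int(d.min())
        winner = min(cids[d == dmin])
        return (float(dmin), str(winner))

    def covering_spans(self, chrom: str, pos: int) -> list[str]:
        probe = GenomicInterval(chrom, pos, pos + 1)
        hits = self.span_index.overlapping(probe)
        return sorted(self.complexes[i].complex_id for i in hits)


def categorize_gene(
    gene: Gene,
    complexes: Sequence[ChromatinComplex] | ComplexIndex,
    config: AnnotationConfig = AnnotationConfig(),
    condition: str = "",
) -> GeneComplexAnnotation:
    """Assign anchor / loop / outside with anchor-precedence and nearest tie-break."""
    index = complexes if isinstance(complexes, ComplexIndex) else ComplexIndex(list(complexes))
    dist, cid = index.nearest_anchor(gene.chrom, gene.tss)
    if dist <= config.anchor_window:
        return GeneComplexAnnotation(gene.gene_id, condition, "anchor", cid, dist)
    covering = index.covering_spans(gene.chrom, gene.tss)
    if covering:
        return GeneComplexAnnotation(gene.gene_id, condition, "loop", covering[0], dist)
    return GeneComplexAnnotation(gene.gene_id, condition, "outside", None, dist)


def annotate_genes(
    genes: Iterable[Gene],
    complexes: Sequence[ChromatinComplex],
    config: AnnotationConfig = AnnotationConfig(),
    condition: str = "",
) -> list[GeneComplexAnnotation]:
    index = ComplexIndex(list(complexes))
    return [categorize_gene(g, index, config, condition) for g in genes]


def assign_standalone(
    gene: Gene,
    standalone_sites: IntervalIndex | Sequence[GenomicInterval],
    config: AnnotationConfig = AnnotationConfig(),
) -> bool:
    """True iff the gene TSS is within ``standalone_window`` of a stand-alone site."""
    idx = (
        standalone_sites
        if isinstance(standalone_sites, IntervalIndex)
        else IntervalIndex(list(standalone_sites))
    )
    return idx.nearest_distance(gene.chrom, gene.tss) <= config.standalone_window


@dataclass
class ComplexContentSummary:
    factor: str
    n_complexes: int
    n_with_site: int
    mean_sites_among_positive: float | None

    @property
    def fraction_with_site(self) -> float | None:
        if self.n_complexes == 0:
            return None
        return self.n_with_site / self.n_complexes


def complex_content(
    complexes: Sequence[ChromatinComplex],
    site_sets: Mapping[str, Sequence[GenomicInterval]],
    in_anchors_only: bool = True,
) -> tuple[dict[str, dict[str, int]], list[ComplexContentSummary]]:
    """Count factor binding sites inside each complex.

    Returns per-complex counts (complex_id -> factor -> n sites) and, per
    factor, the number/fraction of complexes with >=1 site and the mean
    site count among those.
    """
    per_complex: dict[str, dict[str, int]] = {
        cx.complex_id: {} for cx in complexes
    }
    summaries = []
    for factor, sites in site_sets.items():
        site_idx = IntervalIndex(list(sites))
        counts = []
        for cx in complexes:
            regions = cx.anchors if in_anchors_only else [cx.span]
            hit_ids: set[int] = set()
            for r in regions:
                hit_ids.update(site_idx.overlapping(r))
            per_complex[cx.complex_id][factor] = len(hit_ids)
            counts.append(len(hit_ids))
        positives = [c for c in counts if c > 0]
        summaries.append(
            ComplexContentSummary(
                factor=factor,
                n_complexes=len(complexes),
                n_with_site=len(positives),
                mean_sites_among_positive=(
                    float(np.mean(positives)) if positives else None
                ),
            )
        )
    return per_complex, summaries
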