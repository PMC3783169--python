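"""Consensus cistromes across ChIP-seq studies and factor co-occurrence.

Binding-site sets for the same factor vary substantially between studies,
so a consensus cistrome keeps only regions where peaks from at least
``min_studies`` independent studies overlap (>=1 bp, transitively
clustered), emitting the merged span of each supported cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import GenomicInterval, IntervalIndex
from .io import PeakSet


@dataclass(frozen=True)
class ConsensusSite:
    interval: GenomicInterval
    support: int
    study_ids: frozenset[str]


@dataclass(frozen=True)
class CooccurrenceResult:
    n_overlapping: int
    n_total: int

    @property
    def fraction(self) -> float | None:
        if self.n_total == 0:
            return None
        return self.n_overlapping / self.n_total


def consensus_cistrome(
    studies: Sequence[PeakSet], min_studies: int = 2
) -> list[ConsensusSite]:
    """Merge overlapping binding sites supported by >= ``min_studies`` studies.

    Pools all peaks, clusters them transitively by >=1 bp overlap, counts
    distinct contributing studies per cluster, and emits the merged span of
    clusters meeting the support threshold. A study supports a cluster if
    any of its peaks belongs to it (site-level, not base-level, voting).
    """
    if min_studies > len(studies):
        raise ValueError(
            f"min_studies={min_studies} exceeds number of studies ({len(studies)})"
        )
    pool: list[tuple[GenomicInterval, str]] = []
    for st in studies:
        for p in st:
            pool.append((p, st.name))
    pool.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    sites: list[ConsensusSite] = []

    def flush(chrom, start, end, members):
        support = len(members)
        if support >= min_studies:
            sites.append(
                ConsensusSite(
                    GenomicInterval(chrom, start, end), support, frozenset(members)
                )
            )

    cur = None  # (chrom, start, end, member-study set)
    for iv, study in pool:
        if cur is not None and iv.chrom == cur[0] and iv.start < cur[2]:
            cur = (cur[0], cur[1], max(cur[2], iv.end), cur[3] | {study})
        else:
            if cur is not None:
                flush(*cur)
            cur = (iv.chrom, iv.start, iv.end, {study})
    if cur is not None:
        flush(*cur)
    return sites


def cooccurrence_fraction(
    sites: Sequence[GenomicInterval],
    partner_sets: Sequence[PeakSet],
    within: Sequence[GenomicInterval] | None = None,
) -> CooccurrenceResult:
    """Fraction of ``sites`` overlapping >=1 peak of any partner set.

    When ``within`` is given, sites are first restricted to those
    overlapping one of its intervals (e.g. complex regions). An empty
    restricted set yields fraction None (0/0).
    """
    if not partner_sets:
        raise ValueError("no partner sets to test against")
    candidates = list(sites)
    if within is not None:
        widx = IntervalIndex(list(within))
        candidates = [s for s in candidates if widx.overlaps_any(s)]
    partner_idx = IntervalIndex([p for ps in partner_sets for p in ps])
    n_hit = sum(1 for s in candidates if partner_idx.overlaps_any(s))
    return CooccurrenceResult(n_hit, len(candidates))
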