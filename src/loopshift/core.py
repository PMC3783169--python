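"""Coordinate primitives and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` (BED-native).
Distances between a point and an interval are measured to the nearest
*contained* base, so a point one base past ``end`` is at distance 1 and
"within +/- W" rules are boundary-inclusive (distance <= W passes).
Chromosome names are compared as exact strings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Sentinel for "different chromosome" distances.
INF = math.inf

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    """Single-TSS gene model.

    ``tss`` is the position of the first transcribed base: ``tx_start`` on
    the + strand and ``tx_end - 1`` on the - strand, which keeps +/- window
    rules symmetric across strands. ``tes`` is the opposite bound.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid transcript bounds")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


RESPONSE_LABELS = ("induced", "repressed", "nonresponsive")


@dataclass(frozen=True)
class ResponseClass:
    """Estrogen-response label of one gene (consumed, not derived)."""

    gene_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in RESPONSE_LABELS:
            raise ValueError(
                f"unknown response label {self.label!r}; "
                f"allowed: {', '.join(RESPONSE_LABELS)}"
            )


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between two intervals; 0 on overlap, inf across chromosomes."""
    if a.chrom != b.chrom:
        return INF
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def point_to_interval_distance(chrom: str, pos: int, b: GenomicInterval) -> float:
    """Distance from a point to the nearest base contained in ``b``.

    0 when ``b.start <= pos < b.end``; inf when chromosomes differ.
    """
    if chrom != b.chrom:
        return INF
    if b.start <= pos < b.end:
        return 0
    # nearest contained bases are b.start and b.end - 1
    return min(abs(pos - b.start), abs(pos - (b.end - 1)))


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals that overlap or whose gap is <= ``min_gap``.

    Returns intervals sorted by (chrom, start), strand-agnostic. Base
    coverage of the input is preserved exactly when ``min_gap == 0``.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= min_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


class IntervalIndex:
    """Chromosome-indexed interval collection with overlap and nearest queries.

    Built once from an interval sequence; queries run on numpy-sorted
    start/end arrays. Intervals may overlap each other; ``nearest_distance``
    works on the merged silhouette.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._ids: dict[str, np.ndarray] = {}
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            idx.sort(key=lambda i: (self.intervals[i].start, self.intervals[i].end))
            starts = np.array([self.intervals[i].start for i in idx], dtype=np.int64)
            ends = np.array([self.intervals[i].end for i in idx], dtype=np.int64)
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._ids[chrom] = np.array(idx, dtype=np.int64)
            merged = merge_intervals([self.intervals[i] for i in idx])
            self._merged[chrom] = (
                np.array([m.start for m in merged], dtype=np.int64),
                np.array([m.end for m in merged], dtype=np.int64),
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, query: GenomicInterval) -> list[int]:
        """Indices (into the construction order) of intervals overlapping query."""
        if query.chrom not in self._starts:
            return []
        starts = self._starts[query.chrom]
        ends = self._ends[query.chrom]
        # candidate window: starts < query.end; filter by ends > query.start
        hi = int(np.searchsorted(starts, query.end, side="left"))
        mask = ends[:hi] > query.start
        return [int(i) for i in self._ids[query.chrom][:hi][mask]]

    def overlaps_any(self, query: GenomicInterval) -> bool:
        if query.chrom not in self._starts:
            return False
        starts = self._starts[query.chrom]
        ends = self._ends[query.chrom]
        hi = int(np.searchsorted(starts, query.end, side="left"))
        return bool(np.any(ends[:hi] > query.start))

    def nearest_distance(self, chrom: str, pos: int) -> float:
        """Distance from a point to the nearest covered base; inf off-chromosome."""
        if chrom not in self._merged:
            return INF
        mstarts, mends = self._merged[chrom]
        j = int(np.searchsorted(mstarts, pos, side="right")) - 1
        best = INF
        if j >= 0:
            if pos < mends[j]:
                return 0
            best = pos - (int(mends[j]) - 1)
        if j + 1 < len(mstarts):
            best = min(best, int(mstarts[j + 1]) - pos)
        return best


def overlap_any(
    query: GenomicInterval, reference: IntervalIndex | Sequence[GenomicInterval]
) -> tuple[bool, list[int]]:
    """True iff >=1 bp overlap with any reference interval, plus matched indices."""
    index = (
        reference
        if isinstance(reference, IntervalIndex)
        else IntervalIndex(list(reference))
    )
    hits = index.overlapping(query)
    return (len(hits) > 0, hits)
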