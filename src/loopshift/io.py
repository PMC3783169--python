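"""Readers and writers for the on-disk formats the pipeline touches.

Formats: BED3/BED6 (peaks, read tags), BEDPE (chromatin interaction
clusters), bedGraph (strand-specific read-start coverage), refFlat-like
TSV and BED6/BED12 (single-TSS gene models), TSV (response table and all
result tables). Readers reject malformed coordinates with line-numbered
errors rather than silently repairing them.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    Gene,
    GenomicInterval,
    RESPONSE_LABELS,
    ResponseClass,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file; message carries path and line number."""


@dataclass
class PeakSet:
    """A named ChIP-seq peak collection (peaks consumed, never called here)."""

    name: str
    peaks: list[GenomicInterval]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class InteractionPair:
    """One ChIA-PET interaction cluster: two anchor regions held together.

    Inter-chromosomal pairs are readable but flagged; complex assembly
    uses intra-chromosomal pairs only.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    pet_count: int = 1

    @property
    def inter_chromosomal(self) -> bool:
        return self.anchor_a.chrom != self.anchor_b.chrom


class CoverageTrack:
    """Strand-specific per-base read-start counts, run-length encoded.

    Stores sorted non-overlapping runs ``[start, end) -> count`` per
    chromosome; range sums are O(log n) via cumulative totals. RPM
    quantities always normalize by ``library_size`` (total mapped reads
    across both strands, which may exceed the counts stored here).
    """

    def __init__(
        self,
        condition: str,
        strand: str,
        runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: int,
    ):
        if strand not in ("+", "-"):
            raise ValueError("coverage track strand must be + or -")
        self.condition = condition
        self.strand = strand
        self._runs = {}
        self._cum = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.int64)
            if np.any(values < 0):
                raise ValueError("negative coverage value")
            self._runs[chrom] = (starts, ends, values)
            widths = ends - starts
            self._cum[chrom] = np.concatenate(
                [[0], np.cumsum(values * widths)]
            )
        self.library_size = int(library_size)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._runs)

    @property
    def total_count(self) -> int:
        return int(sum(c[-1] for c in self._cum.values()))

    @classmethod
    def from_positions(
        cls,
        condition: str,
        strand: str,
        positions: dict[str, np.ndarray],
        library_size: int | None = None,
    ) -> "CoverageTrack":
        """Build from raw read 5'-end positions (one entry per read)."""
        runs = {}
        total = 0
        for chrom, pos in positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size == 0:
                continue
            uniq, counts = np.unique(pos, return_counts=True)
            runs[chrom] = (uniq, uniq + 1, counts)
            total += int(pos.size)
        return cls(condition, strand, runs, library_size if library_size is not None else total)

    def region_count(self, chrom: str, start: int, end: int) -> int:
        """Total read starts in ``[start, end)``."""
        if chrom not in self._runs or end <= start:
            return 0
        starts, ends, values = self._runs[chrom]
        j0 = int(np.searchsorted(ends, start, side="right"))
        j1 = int(np.searchsorted(starts, end, side="left"))
        if j1 <= j0:
            return 0
        total = int(self._cum[chrom][j1] - self._cum[chrom][j0])
        if starts[j0] < start:
            total -= int(values[j0]) * int(start - starts[j0])
        if ends[j1 - 1] > end:
            total -= int(values[j1 - 1]) * int(ends[j1 - 1] - end)
        return total

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense count vector over ``[start, end)`` (zeros off-track)."""
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self._runs:
            return out
        starts, ends, values = self._runs[chrom]
        j0 = int(np.searchsorted(ends, start, side="right"))
        j1 = int(np.searchsorted(starts, end, side="left"))
        for j in range(j0, j1):
            a = max(int(starts[j]), start) - start
            b = min(int(ends[j]), end) - start
            out[a:b] = values[j]
        return out

    def scaled(self, factor: int) -> "CoverageTrack":
        """Multiply all counts and the library size by an integer factor."""
        runs = {
            c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self._runs.items()
        }
        return CoverageTrack(self.condition, self.strand, runs, self.library_size * factor)


# ---------------------------------------------------------------------------
# BED / BEDPE


def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Read BED3+ into a PeakSet; columns beyond 6 are ignored."""
    path = Path(path)
    peaks: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split(line)
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >=3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from e
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}:{ln}: invalid interval start={start} end={end}"
                )
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            peaks.append(GenomicInterval(f[0], start, end, strand))
    return PeakSet(name=name or path.stem, peaks=peaks, source=str(path))


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Sequence[float] | None = None,
    names: Sequence[str] | None = None,
) -> None:
    ivs = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None or iv.strand != ".":
                cols.append(names[i] if names is not None else f"iv{i}")
                cols.append(str(scores[i]) if scores is not None else "0")
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def read_interactions(path: str | Path) -> list[InteractionPair]:
    """Read BEDPE-style interaction clusters.

    Columns: chromA startA endA chromB startB endB [name] [pet_count].
    """
    path = Path(path)
    pairs: list[InteractionPair] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split(line)
            if len(f) < 6:
                raise FormatError(f"{path}:{ln}: BEDPE needs >=6 columns")
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]))
                b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from e
            pet = int(f[7]) if len(f) >= 8 else 1
            if pet < 0:
                raise FormatError(f"{path}:{ln}: negative PET count")
            pairs.append(InteractionPair(a, b, pet))
    n_inter = sum(p.inter_chromosomal for p in pairs)
    if n_inter:
        log.info("%s: %d inter-chromosomal pairs (excluded from assembly)", path, n_inter)
    return pairs


def write_interactions(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pairs):
            fh.write(
                "\t".join(
                    [
                        p.anchor_a.chrom,
                        str(p.anchor_a.start),
                        str(p.anchor_a.end),
                        p.anchor_b.chrom,
                        str(p.anchor_b.start),
                        str(p.anchor_b.end),
                        f"pair{i}",
                        str(p.pet_count),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genes


@dataclass
class GeneSet:
    """Gene list plus bookkeeping from the single-TSS filter."""

    genes: list[Gene]
    n_dropped_multi_tss: int = 0
    dropped_ids: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def _gene_records_from_file(path: Path) -> list[tuple[str, str, str, int, int]]:
    """Yield (name, chrom, strand, tx_start, tx_end); sniffs refFlat vs BED."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split(line)
            if len(f) >= 5 and f[2] in ("+", "-") and not f[1].isdigit():
                # refFlat-like: geneName chrom strand txStart txEnd
                name, chrom, strand = f[0], f[1], f[2]
                try:
                    s, e = int(f[3]), int(f[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
            elif len(f) >= 6:
                # BED6 / BED12: chrom start end name score strand
                chrom, name, strand = f[0], f[3], f[5]
                try:
                    s, e = int(f[1]), int(f[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
            else:
                raise FormatError(f"{path}:{ln}: unrecognized gene record")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{ln}: unknown strand symbol {strand!r}")
            if s >= e or s < 0:
                raise FormatError(f"{path}:{ln}: invalid transcript bounds")
            records.append((name, chrom, strand, s, e))
    return records


def read_genes(path: str | Path, require_single_tss: bool = True) -> GeneSet:
    """Read gene models; genes with >1 distinct annotated TSS are dropped.

    Accepts refFlat-like TSV (geneName chrom strand txStart txEnd) or
    BED6/BED12. Records of one gene sharing a TSS are collapsed to the
    longest transcript.
    """
    path = Path(path)
    by_name: dict[str, list[tuple[str, str, int, int]]] = {}
    order: list[str] = []
    for name, chrom, strand, s, e in _gene_records_from_file(path):
        if name not in by_name:
            order.append(name)
        by_name.setdefault(name, []).append((chrom, strand, s, e))
    genes: list[Gene] = []
    dropped: list[str] = []
    for name in order:
        recs = by_name[name]
        tss_values = {
            (chrom, s if strand == "+" else e - 1) for chrom, strand, s, e in recs
        }
        if require_single_tss and len(tss_values) > 1:
            dropped.append(name)
            continue
        chrom, strand, s, e = max(recs, key=lambda r: r[3] - r[2])
        genes.append(Gene(name, chrom, strand, s, e))
    if dropped:
        log.info(
            "%s: dropped %d genes with multiple annotated TSSs", path, len(dropped)
        )
    return GeneSet(genes=genes, n_dropped_multi_tss=len(dropped), dropped_ids=dropped)


def write_genes(genes: Iterable[Gene], path: str | Path) -> None:
    """Write refFlat-like TSV (geneName chrom strand txStart txEnd)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join([g.gene_id, g.chrom, g.strand, str(g.tx_start), str(g.tx_end)])
                + "\n"
            )


# ---------------------------------------------------------------------------
# Coverage


def _read_strand_positions(path: Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Parse bedGraph runs or BED6 read tags into per-chrom runs."""
    runs: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _split(line)
            if len(f) == 4:
                # bedGraph: chrom start end value
                try:
                    s, e, v = int(f[1]), int(f[2]), int(f[3])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{ln}: bedGraph values must be integers"
                    ) from exc
            elif len(f) >= 6:
                # BED6 read tag: count its 5'-end once
                s = int(f[1])
                e = s + 1
                v = 1
            else:
                raise FormatError(f"{path}:{ln}: expected bedGraph or BED6")
            if v < 0:
                raise FormatError(f"{path}:{ln}: negative value")
            if s >= e or s < 0:
                raise FormatError(f"{path}:{ln}: invalid run {s}-{e}")
            if v > 0:
                runs.setdefault(f[0], []).append((s, e, v))
    out = {}
    for chrom, rr in runs.items():
        rr.sort()
        starts = np.array([r[0] for r in rr], dtype=np.int64)
        ends = np.array([r[1] for r in rr], dtype=np.int64)
        vals = np.array([r[2] for r in rr], dtype=np.int64)
        if np.any(starts[1:] < ends[:-1]):
            if np.any(ends - starts != 1):
                raise FormatError(f"{path}: overlapping bedGraph runs on {chrom}")
            # BED6 read tags repeat positions: aggregate per 5'-end
            expand = np.repeat(starts, vals)
            uniq, counts = np.unique(expand, return_counts=True)
            starts, ends, vals = uniq, uniq + 1, counts
        out[chrom] = (starts, ends, vals)
    return out


def read_coverage(
    path_plus: str | Path,
    path_minus: str | Path,
    library_size: int | None = None,
    condition: str = "cov",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Read a strand pair of coverage files (bedGraph runs or BED6 tags).

    When ``library_size`` is omitted it defaults to the total count across
    both strand files, making RPM self-contained.
    """
    plus_runs = _read_strand_positions(Path(path_plus))
    minus_runs = _read_strand_positions(Path(path_minus))
    plus = CoverageTrack(condition, "+", plus_runs, 1)
    minus = CoverageTrack(condition, "-", minus_runs, 1)
    lib = library_size if library_size is not None else plus.total_count + minus.total_count
    if lib <= 0:
        raise ValueError("library size must be positive")
    plus.library_size = int(lib)
    minus.library_size = int(lib)
    return plus, minus


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            starts, ends, values = track._runs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# Response table and result tables


def read_response_table(path: str | Path) -> list[ResponseClass]:
    """Read TSV ``gene_id <tab> label``; labels must be one of the known set."""
    path = Path(path)
    seen: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split(line)
            if len(f) < 2:
                raise FormatError(f"{path}:{ln}: need gene_id<TAB>label")
            gid, label = f[0], f[1]
            if gid == "gene_id":  # header
                continue
            if label not in RESPONSE_LABELS:
                raise FormatError(
                    f"{path}:{ln}: unknown label {label!r}; "
                    f"allowed: {', '.join(RESPONSE_LABELS)}"
                )
            if gid in seen:
                if seen[gid] != label:
                    raise FormatError(
                        f"{path}:{ln}: gene {gid} has conflicting labels "
                        f"{seen[gid]!r} and {label!r}"
                    )
                log.warning("%s:%d: duplicate consistent row for %s", path, ln, gid)
                continue
            seen[gid] = label
            order.append(gid)
    return [ResponseClass(g, seen[g]) for g in order]


def config_hash(obj) -> str:
    """Stable short hash of a configuration object for table headers."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, config=None
) -> None:
    """Write a result table as TSV with a ``#`` comment header block."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
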