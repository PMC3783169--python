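"""RPM normalization, metagene profiles, initiation rates, pause ratios.

All read quantities are reads-per-million (RPM): raw read-start counts
scaled by 1e6 / library size. Metagene profiles align genes at TSS and
TES, keep fixed per-bp flanks, and rescale each variable-length gene body
to 100 bins via a natural cubic spline evaluated at 1000 equispaced
points. The pause ratio contrasts nascent-transcription density in the
TSS +/-300 bp window with density over the gene body (TSS+300 bp to TES),
both as RPM per kb; high values indicate promoter-proximal Pol II pausing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .core import Gene, GenomicInterval
from .io import CoverageTrack
from .transitions import TTestResult, group_mean_test


@dataclass(frozen=True)
class ProfileConfig:
    flank: int = 500  # 500 bp for Pol II ChIP profiles, 1000 for GRO-seq
    body_points: int = 1000
    body_bins: int = 100
    tss_window: int = 300
    min_gene_length: int = 2_000  # minimal body length kept for spline scaling

    def __post_init__(self) -> None:
        if self.body_points % self.body_bins:
            raise ValueError("body_points must be divisible by body_bins")
        if self.flank <= 0 or self.tss_window <= 0:
            raise ValueError("flank and tss_window must be positive")


@dataclass
class MetageneProfile:
    promoter: np.ndarray  # per-bp RPM, length 2*flank, TSS at index flank
    body: np.ndarray  # body_bins RPM values
    tes: np.ndarray  # per-bp RPM, length 2*flank, TES at index flank
    n_genes: int
    n_skipped_short: int


@dataclass(frozen=True)
class PauseStats:
    gene_id: str
    condition: str
    tss_density: float  # RPM per kb, sense strand, TSS +/- tss_window
    body_density: float  # RPM per kb, TSS+tss_window .. TES
    pause_ratio: float | None  # None when undefined (zero body, no pseudocount)
    antisense_tss_rpm: float


def region_rpm(track: CoverageTrack, region: GenomicInterval) -> float:
    """Reads-per-million in a region: counts * 1e6 / library_size."""
    if track.library_size <= 0:
        raise ValueError("library size must be positive for RPM")
    return track.region_count(region.chrom, region.start, region.end) * 1e6 / track.library_size


def _oriented_window(gene: Gene, center: int, upstream: int, downstream: int) -> tuple[int, int]:
    """Genomic [start, end) covering gene-oriented offsets [-upstream, downstream)."""
    if gene.strand == "+":
        return center - upstream, center + downstream
    return center - downstream + 1, center + upstream + 1


def tss_window_interval(gene: Gene, half_width: int) -> GenomicInterval:
    s, e = _oriented_window(gene, gene.tss, half_width, half_width)
    return GenomicInterval(gene.chrom, max(0, s), e)


def body_interval(gene: Gene, downstream_offset: int) -> GenomicInterval | None:
    """Gene body from ``downstream_offset`` bp past the TSS to the TES."""
    if gene.length <= downstream_offset:
        return None
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, gene.tx_start + downstream_offset, gene.tx_end)
    return GenomicInterval(gene.chrom, gene.tx_start, gene.tx_end - downstream_offset)


def _per_base_oriented(track: CoverageTrack, gene: Gene, start: int, end: int) -> np.ndarray:
    arr = track.per_base(gene.chrom, start, end)
    return arr if gene.strand == "+" else arr[::-1]


def _tracks_for_gene(
    tracks: CoverageTrack | tuple[CoverageTrack, CoverageTrack],
    gene: Gene,
    strand_mode: str,
) -> list[CoverageTrack]:
    if isinstance(tracks, CoverageTrack):
        return [tracks]
    plus, minus = tracks
    if strand_mode == "unstranded":
        return [plus, minus]
    sense = plus if gene.strand == "+" else minus
    anti = minus if gene.strand == "+" else plus
    return [sense] if strand_mode == "sense" else [anti]


def metagene_profile(
    genes: Sequence[Gene],
    tracks: CoverageTrack | tuple[CoverageTrack, CoverageTrack],
    config: ProfileConfig = ProfileConfig(),
    strand_mode: str = "unstranded",
) -> MetageneProfile:
    """Average TSS/body/TES profile over genes, bodies spline-scaled to bins.

    Per gene (in gene orientation, - strand flipped): per-bp RPM over
    [TSS-flank, TSS+flank); body over [TSS+flank, TES-flank) interpolated
    with a natural cubic spline at ``body_points`` equispaced points
    (negatives clipped to 0) and averaged into ``body_bins`` bins; per-bp
    RPM around the TES. The metagene is the per-position/bin mean.
    """
    if strand_mode not in ("unstranded", "sense", "antisense"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    lib = (tracks if isinstance(tracks, CoverageTrack) else tracks[0]).library_size
    if lib <= 0:
        raise ValueError("library size must be positive")
    prom_sum = np.zeros(2 * config.flank)
    body_sum = np.zeros(config.body_bins)
    tes_sum = np.zeros(2 * config.flank)
    n_used = 0
    n_short = 0
    for gene in genes:
        body_len = gene.length - 2 * config.flank
        if body_len < config.min_gene_length:
            n_short += 1
            continue
        use = _tracks_for_gene(tracks, gene, strand_mode)
        # gene-oriented genomic windows
        ps, pe = _oriented_window(gene, gene.tss, config.flank, config.flank)
        ts, te = _oriented_window(gene, gene.tes, config.flank, config.flank)
        if gene.strand == "+":
            bs, be = gene.tx_start + config.flank, gene.tx_end - config.flank
        else:
            bs, be = gene.tx_start + config.flank, gene.tx_end - config.flank
        prom = sum(_per_base_oriented(t, gene, ps, pe) for t in use)
        tes = sum(_per_base_oriented(t, gene, ts, te) for t in use)
        body = sum(_per_base_oriented(t, gene, bs, be) for t in use)
        x = np.arange(body.size)
        spline = CubicSpline(x, body, bc_type="natural")
        pts = np.clip(spline(np.linspace(0, body.size - 1, config.body_points)), 0, None)
        binned = pts.reshape(config.body_bins, -1).mean(axis=1)
        prom_sum += prom
        tes_sum += tes
        body_sum += binned
        n_used += 1
    if n_used == 0:
        raise ValueError("no gene passed the minimum body-length filter")
    scale = 1e6 / lib
    return MetageneProfile(
        promoter=prom_sum / n_used * scale,
        body=body_sum / n_used * scale,
        tes=tes_sum / n_used * scale,
        n_genes=n_used,
        n_skipped_short=n_short,
    )


def initiation_rate(
    gene: Gene,
    plus_track: CoverageTrack,
    minus_track: CoverageTrack,
    config: ProfileConfig = ProfileConfig(),
) -> tuple[float, float]:
    """(sense RPM, antisense RPM) in the TSS window (+/- tss_window bp)."""
    win = tss_window_interval(gene, config.tss_window)
    sense_track = plus_track if gene.strand == "+" else minus_track
    anti_track = minus_track if gene.strand == "+" else plus_track
    return region_rpm(sense_track, win), region_rpm(anti_track, win)


def pause_ratio(
    gene: Gene,
    plus_track: CoverageTrack,
    minus_track: CoverageTrack,
    config: ProfileConfig = ProfileConfig(),
    pseudocount_reads: float = 1.0,
    condition: str = "",
    min_body_length: int = 300,
) -> PauseStats | None:
    """Pause ratio = TSS-window density / gene-body density (RPM per kb).

    The body starts ``tss_window`` bp downstream of the TSS and runs to the
    TES. Returns None for genes whose body would be shorter than
    ``min_body_length``. ``pseudocount_reads`` is added to the raw counts
    of both regions before converting to densities; with pseudocount 0 a
    zero-read body yields an undefined (None) ratio, flagged in PauseStats.
    """
    body = body_interval(gene, config.tss_window)
    if body is None or body.length < min_body_length:
        return None
    win = tss_window_interval(gene, config.tss_window)
    sense = plus_track if gene.strand == "+" else minus_track
    anti = minus_track if gene.strand == "+" else plus_track
    lib = sense.library_size
    tss_reads = sense.region_count(win.chrom, win.start, win.end) + pseudocount_reads
    body_reads = sense.region_count(body.chrom, body.start, body.end) + pseudocount_reads
    tss_density = tss_reads * 1e6 / lib / (win.length / 1000)
    body_density = body_reads * 1e6 / lib / (body.length / 1000)
    ratio = tss_density / body_density if body_density > 0 else None
    return PauseStats(
        gene_id=gene.gene_id,
        condition=condition,
        tss_density=tss_density,
        body_density=body_density,
        pause_ratio=ratio,
        antisense_tss_rpm=region_rpm(anti, win),
    )


@dataclass
class ConditionComparison:
    metric: str
    test: TTestResult
    median_before: float
    median_after: float
    direction: str  # increase | decrease | none
    n_genes: int


def compare_conditions(
    stats_before: Sequence[PauseStats],
    stats_after: Sequence[PauseStats],
    metric: str = "pause_ratio",
    paired: bool = True,
) -> ConditionComparison:
    """Paired comparison of a per-gene metric between conditions."""
    before = {s.gene_id: getattr(s, metric) for s in stats_before}
    after = {s.gene_id: getattr(s, metric) for s in stats_after}
    shared = [
        g
        for g in before
        if g in after and before[g] is not None and after[g] is not None
    ]
    if len(shared) < 2:
        raise ValueError("need >=2 shared genes with defined metric values")
    a = np.array([after[g] for g in shared], dtype=float)
    b = np.array([before[g] for g in shared], dtype=float)
    test = group_mean_test(a, b, paired=paired)
    med_b, med_a = float(np.median(b)), float(np.median(a))
    direction = "none" if med_a == med_b else ("increase" if med_a > med_b else "decrease")
    return ConditionComparison(metric, test, med_b, med_a, direction, len(shared))
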