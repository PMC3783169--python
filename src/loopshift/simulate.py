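"""Synthetic study generator with per-gene truth labels.

Emits a fully self-consistent miniature of the study's input bundle:
single-TSS genes with estrogen-response labels, pre-treatment Pol II
chromatin complexes (BEDPE interaction chains), pre-treatment ERα
binding sites replicated across noisy pseudo-studies, pioneer-factor
peaks enriched in anchors, post-treatment ERα complexes that retain or
disrupt the pre-treatment ones at class-specific probabilities,
stand-alone post-treatment sites, and strand-specific GRO-seq-like
read-start coverage with class-dependent pause ratios.

Construction is truth-first: signal is placed to match sampled labels,
and the truth table is then re-derived from the emitted geometry by an
independent brute-force scan, so truth always agrees with the files even
when placements interact (e.g. a gene falling inside an unrelated span is
labelled loop). Complexes are built one per responsive gene — disruption
is sampled per complex from the response class of the gene it encloses —
plus background complexes that contain no responsive TSS. Genes are
placed with a minimum TSS separation so an anchor covering one TSS can
never sit inside the +/-5 kb window of another.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import Gene, GenomicInterval, ResponseClass
from .io import (
    CoverageTrack,
    InteractionPair,
    PeakSet,
    write_bed,
    write_bedgraph,
    write_genes,
    write_interactions,
)


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 5_000_000
    n_genes: int = 800
    gene_length_log_mean: float = 9.5
    gene_length_log_sd: float = 0.6
    gene_length_min: int = 2_000
    gene_length_max: int = 200_000
    frac_induced: float = 0.30
    frac_repressed: float = 0.25
    class_counts: tuple[int, int, int] | None = None  # (induced, repressed, nonresponsive)
    n_background_complexes: int = 250
    anchor_extra_poisson: float = 1.0  # anchors per complex = 2 + Poisson(this)
    anchor_width_min: int = 1_000
    anchor_width_max: int = 4_000
    p_tss_in_anchor: float = 0.9
    er_sites_per_complex: float = 3.0
    er_background_per_bp: float = 1 / 500_000
    n_pseudo_studies: int = 3
    study_dropout: float = 0.2
    study_jitter: int = 150
    pause_log_mean_induced: float = float(np.log(8))
    pause_log_mean_repressed: float = float(np.log(2))
    pause_log_mean_nonresponsive: float = float(np.log(3))
    pause_log_sd: float = 0.4
    reads_per_library: int = 2_000_000
    antisense_frac: float = 0.2
    k_elong: float = 3.0  # induced: post-treatment body density multiplier
    k_rep: float = 0.4  # repressed: post-treatment sense (TSS and body) multiplier
    antisense_post_factor: float = 0.5  # repressed antisense multiplier
    d_repressed: float = 0.86
    d_induced: float = 0.49
    p_standalone_given_disrupted: float = 0.4
    p_loop_given_disrupted: float = 0.4
    anchor_window: int = 5_000
    standalone_window: int = 20_000
    tss_window: int = 300
    min_tss_separation: int = 12_000

    def __post_init__(self) -> None:
        for p in (
            self.frac_induced,
            self.frac_repressed,
            self.p_tss_in_anchor,
            self.study_dropout,
            self.d_repressed,
            self.d_induced,
            self.p_standalone_given_disrupted,
            self.p_loop_given_disrupted,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.frac_induced + self.frac_repressed > 1:
            raise ValueError("class fractions sum above 1")
        if self.p_standalone_given_disrupted + self.p_loop_given_disrupted > 1:
            raise ValueError("disruption-outcome probabilities sum above 1")

    def counts(self) -> tuple[int, int, int]:
        if self.class_counts is not None:
            return self.class_counts
        n_ind = round(self.n_genes * self.frac_induced)
        n_rep = round(self.n_genes * self.frac_repressed)
        return (n_ind, n_rep, self.n_genes - n_ind - n_rep)


@dataclass
class _SimComplex:
    complex_id: str
    chrom: str
    anchors: list[GenomicInterval]
    gene_id: str | None  # responsive gene it encloses, None for background
    response: str | None
    intended_category: str | None  # anchor | loop for its gene
    disrupted: bool | None = None
    outcome: str | None = None  # retained | loop | stand-alone | none

    @property
    def span(self) -> tuple[int, int]:
        return (min(a.start for a in self.anchors), max(a.end for a in self.anchors))


@dataclass
class SimResult:
    config: SimConfig
    out_dir: Path
    files: dict[str, Path]
    genes: list[Gene]
    response: list[ResponseClass]
    truth: pd.DataFrame
    truth_complexes: pd.DataFrame
    chrom_sizes: dict[str, int]
    library_sizes: dict[str, int]


class _Occupancy:
    """Per-chromosome sorted disjoint intervals with overlap tests."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def overlaps(self, chrom: str, start: int, end: int, pad: int = 0) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        ends = self._ends[chrom]
        i = bisect.bisect_left(starts, end + pad)
        return i > 0 and ends[i - 1] > start - pad

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def _point_interval_dist(pos: int, start: int, end: int) -> int:
    if start <= pos < end:
        return 0
    return min(abs(pos - start), abs(pos - (end - 1)))


class _Simulator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
        self.sizes = {c: config.chrom_length for c in self.chroms}
        self.tss_by_chrom: dict[str, list[int]] = {c: [] for c in self.chroms}

    # -- gene placement ---------------------------------------------------

    def place_genes(self) -> tuple[list[Gene], list[ResponseClass]]:
        cfg = self.cfg
        n_ind, n_rep, n_non = cfg.counts()
        n = n_ind + n_rep + n_non
        lengths = np.clip(
            self.rng.lognormal(cfg.gene_length_log_mean, cfg.gene_length_log_sd, n),
            cfg.gene_length_min,
            cfg.gene_length_max,
        ).astype(int)
        order = np.argsort(-lengths)  # longest-first packing
        occupied = _Occupancy()
        margin = 60_000
        placed: list[tuple[str, int, int, str]] = [None] * n  # type: ignore
        for gi in order:
            length = int(lengths[gi])
            ok = False
            for _ in range(2_000):
                chrom = self.chroms[int(self.rng.integers(len(self.chroms)))]
                hi = cfg.chrom_length - length - margin
                if hi <= margin:
                    continue
                start = int(self.rng.integers(margin, hi))
                end = start + length
                strand = "+" if self.rng.random() < 0.5 else "-"
                tss = start if strand == "+" else end - 1
                if occupied.overlaps(chrom, start, end, pad=2_000):
                    continue
                tl = self.tss_by_chrom[chrom]
                i = bisect.bisect_left(tl, tss)
                near = (i > 0 and tss - tl[i - 1] < cfg.min_tss_separation) or (
                    i < len(tl) and tl[i] - tss < cfg.min_tss_separation
                )
                if near:
                    continue
                occupied.add(chrom, start, end)
                bisect.insort(tl, tss)
                placed[gi] = (chrom, start, end, strand)
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    "could not place genes without overlap; increase chrom_length "
                    "or reduce n_genes"
                )
        # deterministic ids by genomic position
        pos_order = sorted(range(n), key=lambda i: (placed[i][0], placed[i][1]))
        genes = []
        for k, i in enumerate(pos_order, start=1):
            chrom, s, e, strand = placed[i]
            genes.append(Gene(f"g{k:04d}", chrom, strand, s, e))
        labels = np.array(
            ["induced"] * n_ind + ["repressed"] * n_rep + ["nonresponsive"] * n_non
        )
        labels = labels[self.rng.permutation(n)]
        response = [ResponseClass(g.gene_id, str(l)) for g, l in zip(genes, labels)]
        return genes, response

    # -- anchor placement helpers ----------------------------------------

    def _tss_conflict(self, chrom: str, start: int, end: int, allowed: set[int]) -> bool:
        w = self.cfg.anchor_window
        tl = self.tss_by_chrom[chrom]
        i = bisect.bisect_left(tl, start - w)
        j = bisect.bisect_right(tl, end - 1 + w)
        return any(t not in allowed for t in tl[i:j])

    def _place_anchor(
        self,
        occ: _Occupancy,
        chrom: str,
        start0: int,
        width: int,
        allowed: set[int],
        step: int = 3_000,
        attempts: int = 80,
        direction: int = 1,
    ) -> GenomicInterval | None:
        """First conflict-free position scanning from start0 along direction."""
        for k in range(attempts):
            s = start0 + direction * k * step
            e = s + width
            if s < 0 or e > self.cfg.chrom_length:
                return None
            if occ.overlaps(chrom, s, e):
                continue
            if self._tss_conflict(chrom, s, e, allowed):
                continue
            occ.add(chrom, s, e)
            return GenomicInterval(chrom, s, e)
        return None

    def _build_complex_for_gene(
        self, gene: Gene, category: str, occ: _Occupancy, cid: str, response: str
    ) -> _SimComplex:
        cfg = self.cfg
        rng = self.rng
        n_anchors = 2 + int(rng.poisson(cfg.anchor_extra_poisson))
        widths = rng.integers(cfg.anchor_width_min, cfg.anchor_width_max + 1, n_anchors)
        anchors: list[GenomicInterval] = []
        allowed = {gene.tss}
        if category == "anchor":
            w0 = int(widths[0])
            s0 = gene.tss - int(rng.integers(0, w0))
            anchors.append(GenomicInterval(gene.chrom, s0, s0 + w0))
            occ.add(gene.chrom, s0, s0 + w0)
            cursor = s0 + w0
            for wi in widths[1:]:
                gap = int(rng.integers(8_000, 30_000))
                a = self._place_anchor(occ, gene.chrom, cursor + gap, int(wi), allowed)
                if a is None:
                    break
                anchors.append(a)
                cursor = a.end
        else:  # loop: flanking anchors, TSS inside span but off-anchor
            off_l = int(rng.integers(5_500, 15_000))
            wl = int(widths[0])
            a_l = self._place_anchor(
                occ, gene.chrom, gene.tss - off_l - wl, wl, allowed, direction=-1
            )
            off_r = int(rng.integers(5_500, 15_000))
            a_r = self._place_anchor(occ, gene.chrom, gene.tss + off_r, int(widths[1]), allowed)
            if a_l is None or a_r is None:
                # degenerate placement: fall back to anchors further out
                if a_l is None:
                    a_l = self._place_anchor(
                        occ, gene.chrom, gene.tss - 40_000 - wl, wl, allowed, direction=-1
                    )
                if a_r is None:
                    a_r = self._place_anchor(
                        occ, gene.chrom, gene.tss + 40_000, int(widths[1]), allowed
                    )
            if a_l is None or a_r is None:
                raise RuntimeError("could not place loop-complex anchors")
            anchors.extend([a_l, a_r])
            cursor = a_r.end
            for wi in widths[2:]:
                gap = int(rng.integers(8_000, 30_000))
                a = self._place_anchor(occ, gene.chrom, cursor + gap, int(wi), allowed)
                if a is None:
                    break
                anchors.append(a)
                cursor = a.end
        anchors.sort(key=lambda a: a.start)
        return _SimComplex(cid, gene.chrom, anchors, gene.gene_id, response, category)

    def _build_background_complex(self, occ: _Occupancy, cid: str) -> _SimComplex | None:
        cfg = self.cfg
        rng = self.rng
        chrom = self.chroms[int(rng.integers(len(self.chroms)))]
        n_anchors = 2 + int(rng.poisson(cfg.anchor_extra_poisson))
        widths = rng.integers(cfg.anchor_width_min, cfg.anchor_width_max + 1, n_anchors)
        start = int(rng.integers(10_000, cfg.chrom_length - 200_000))
        anchors: list[GenomicInterval] = []
        cursor = start
        for wi in widths:
            a = self._place_anchor(occ, chrom, cursor, int(wi), set())
            if a is None:
                break
            anchors.append(a)
            cursor = a.end + int(rng.integers(8_000, 30_000))
        if len(anchors) < 2:
            return None
        return _SimComplex(cid, chrom, anchors, None, None, None)

    @staticmethod
    def _chain_pairs(cx: _SimComplex, rng: np.random.Generator) -> list[InteractionPair]:
        pairs = []
        for a, b in zip(cx.anchors[:-1], cx.anchors[1:]):
            pairs.append(InteractionPair(a, b, pet_count=2 + int(rng.poisson(3))))
        return pairs

    # -- ER sites ----------------------------------------------------------

    def _sites_in_complexes(self, complexes: list[_SimComplex]) -> list[GenomicInterval]:
        cfg = self.cfg
        rng = self.rng
        sites = []
        for cx in complexes:
            for _ in range(int(rng.poisson(cfg.er_sites_per_complex))):
                anchor = cx.anchors[int(rng.integers(len(cx.anchors)))]
                width = int(rng.integers(200, 601))
                if anchor.length <= width:
                    sites.append(anchor)
                    continue
                s = anchor.start + int(rng.integers(0, anchor.length - width))
                sites.append(GenomicInterval(cx.chrom, s, s + width))
        return sites

    def _background_sites(self, rate_per_bp: float) -> list[GenomicInterval]:
        rng = self.rng
        sites = []
        for chrom in self.chroms:
            for _ in range(int(rng.poisson(rate_per_bp * self.cfg.chrom_length))):
                width = int(rng.integers(200, 601))
                s = int(rng.integers(0, self.cfg.chrom_length - width))
                sites.append(GenomicInterval(chrom, s, s + width))
        return sites

    # -- coverage ----------------------------------------------------------

    def _gro_intensities(self, genes, response_map):
        """Per-gene Poisson intensities (unscaled) for both conditions."""
        cfg = self.cfg
        rng = self.rng
        rows = []
        for g in genes:
            label = response_map[g.gene_id]
            mu = {
                "induced": cfg.pause_log_mean_induced,
                "repressed": cfg.pause_log_mean_repressed,
                "nonresponsive": cfg.pause_log_mean_nonresponsive,
            }[label]
            pr = float(rng.lognormal(mu, cfg.pause_log_sd))
            body_rate = float(rng.lognormal(np.log(5), 0.5))  # reads per kb, relative
            body_kb = max(g.length - cfg.tss_window, 1) / 1000
            lam_tss = pr * body_rate * (2 * cfg.tss_window / 1000)
            lam_body = body_rate * body_kb
            lam_anti = cfg.antisense_frac * lam_tss
            if label == "induced":
                post = (lam_tss, lam_body * cfg.k_elong, lam_anti)
                pr_post = pr / cfg.k_elong
            elif label == "repressed":
                post = (
                    lam_tss * cfg.k_rep,
                    lam_body * cfg.k_rep,
                    lam_anti * cfg.antisense_post_factor,
                )
                pr_post = pr
            else:
                post = (lam_tss, lam_body, lam_anti)
                pr_post = pr
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "pre": (lam_tss, lam_body, lam_anti),
                    "post": post,
                    "pr_pre": pr,
                    "pr_post": pr_post,
                }
            )
        return rows

    def _sample_condition_reads(self, genes, intensities, key):
        """Draw read-start positions; returns (plus, minus) CoverageTracks."""
        cfg = self.cfg
        rng = self.rng
        total = sum(sum(r[key]) for r in intensities)
        f = cfg.reads_per_library / total
        pos: dict[str, dict[str, list[np.ndarray]]] = {
            "+": {c: [] for c in self.chroms},
            "-": {c: [] for c in self.chroms},
        }
        gene_by_id = {g.gene_id: g for g in genes}
        for row in intensities:
            g = gene_by_id[row["gene_id"]]
            lam_tss, lam_body, lam_anti = (x * f for x in row[key])
            w = cfg.tss_window
            if g.strand == "+":
                tss_lo, tss_hi = g.tss - w, g.tss + w
                body_lo, body_hi = g.tx_start + w, g.tx_end
            else:
                tss_lo, tss_hi = g.tss - w + 1, g.tss + w + 1
                body_lo, body_hi = g.tx_start, g.tx_end - w
            sense, anti = (g.strand, "-" if g.strand == "+" else "+")
            n_tss = int(rng.poisson(lam_tss))
            n_body = int(rng.poisson(lam_body))
            n_anti = int(rng.poisson(lam_anti))
            if n_tss:
                pos[sense][g.chrom].append(rng.integers(tss_lo, tss_hi, n_tss))
            if n_body and body_hi > body_lo:
                pos[sense][g.chrom].append(rng.integers(body_lo, body_hi, n_body))
            if n_anti:
                pos[anti][g.chrom].append(rng.integers(tss_lo, tss_hi, n_anti))
        merged = {
            strand: {
                c: (np.concatenate(v) if v else np.empty(0, dtype=np.int64))
                for c, v in chrom_map.items()
            }
            for strand, chrom_map in pos.items()
        }
        lib = int(sum(arr.size for m in merged.values() for arr in m.values()))
        plus = CoverageTrack.from_positions("cond", "+", merged["+"], lib)
        minus = CoverageTrack.from_positions("cond", "-", merged["-"], lib)
        return plus, minus


def simulate(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Generate the full synthetic study bundle into ``out_dir``."""
    sim = _Simulator(config)
    cfg = config
    rng = sim.rng
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes, response = sim.place_genes()
    response_map = {r.gene_id: r.label for r in response}

    # -- pre-treatment Pol II complexes
    pre_occ = _Occupancy()
    pre_complexes: list[_SimComplex] = []
    k = 0
    for g in genes:
        if response_map[g.gene_id] == "nonresponsive":
            continue
        k += 1
        category = "anchor" if rng.random() < cfg.p_tss_in_anchor else "loop"
        pre_complexes.append(
            sim._build_complex_for_gene(
                g, category, pre_occ, f"P{k:04d}", response_map[g.gene_id]
            )
        )
    for _ in range(cfg.n_background_complexes):
        k += 1
        cx = sim._build_background_complex(pre_occ, f"P{k:04d}")
        if cx is not None:
            pre_complexes.append(cx)

    # -- pre-treatment ER sites, pseudo-studies, pioneers
    er_true = sim._sites_in_complexes(pre_complexes) + sim._background_sites(
        cfg.er_background_per_bp
    )
    er_true.sort(key=lambda s: (s.chrom, s.start, s.end))
    studies: list[list[GenomicInterval]] = []
    for _ in range(cfg.n_pseudo_studies):
        st = []
        for s in er_true:
            if rng.random() < cfg.study_dropout:
                continue
            ds = int(rng.integers(-cfg.study_jitter, cfg.study_jitter + 1)) if cfg.study_jitter else 0
            de = int(rng.integers(-cfg.study_jitter, cfg.study_jitter + 1)) if cfg.study_jitter else 0
            ns, ne = max(0, s.start + ds), s.end + de
            if ne <= ns:
                ne = ns + 50
            st.append(GenomicInterval(s.chrom, ns, ne))
        studies.append(sorted(st, key=lambda s: (s.chrom, s.start, s.end)))

    pioneers: dict[str, list[GenomicInterval]] = {"foxa1": [], "gata3": []}
    for factor, p_hit in (("foxa1", 0.7), ("gata3", 0.5)):
        hits = []
        for s in er_true:
            if rng.random() < p_hit:
                shift = int(rng.integers(-100, 101))
                width = int(rng.integers(200, 601))
                ns = max(0, s.start + shift)
                hits.append(GenomicInterval(s.chrom, ns, ns + width))
        hits += sim._background_sites(cfg.er_background_per_bp)
        pioneers[factor] = sorted(hits, key=lambda s: (s.chrom, s.start, s.end))

    # -- disruption sampling and post-treatment ER complexes
    post_occ = _Occupancy()
    er_complexes: list[_SimComplex] = []
    standalone_genes: list[Gene] = []
    gene_by_id = {g.gene_id: g for g in genes}
    m = 0
    for cx in pre_complexes:
        if cx.gene_id is None:
            continue
        d = cfg.d_repressed if cx.response == "repressed" else cfg.d_induced
        disrupted = bool(rng.random() < d)
        cx.disrupted = disrupted
        g = gene_by_id[cx.gene_id]
        if not disrupted:
            cx.outcome = "retained"
            m += 1
            # same anchors re-emitted as an ER complex
            for a in cx.anchors:
                post_occ.add(a.chrom, a.start, a.end)
            er_complexes.append(
                _SimComplex(f"E{m:04d}", cx.chrom, list(cx.anchors), cx.gene_id, cx.response, "anchor")
            )
        else:
            u = rng.random()
            if u < cfg.p_standalone_given_disrupted:
                cx.outcome = "stand-alone"
                standalone_genes.append(g)
            elif u < cfg.p_standalone_given_disrupted + cfg.p_loop_given_disrupted:
                cx.outcome = "loop"
                m += 1
                er_complexes.append(
                    sim._build_complex_for_gene(g, "loop", post_occ, f"E{m:04d}", cx.response)
                )
            else:
                cx.outcome = "none"
    for _ in range(cfg.n_background_complexes):
        m += 1
        cx = sim._build_background_complex(post_occ, f"E{m:04d}")
        if cx is not None:
            er_complexes.append(cx)

    # -- stand-alone post-treatment sites (never overlapping ER anchors)
    standalone_sites: list[GenomicInterval] = []
    for g in standalone_genes:
        for _ in range(60):
            width = int(rng.integers(200, 601))
            off = int(rng.integers(2_000, cfg.standalone_window - 2_000))
            side = 1 if rng.random() < 0.5 else -1
            s = g.tss + side * off
            if s < 0 or s + width > cfg.chrom_length:
                continue
            if post_occ.overlaps(g.chrom, s, s + width):
                continue
            standalone_sites.append(GenomicInterval(g.chrom, s, s + width))
            break
        else:
            raise RuntimeError("could not place a stand-alone site")
    for s in sim._background_sites(cfg.er_background_per_bp):
        if not post_occ.overlaps(s.chrom, s.start, s.end):
            standalone_sites.append(s)
    standalone_sites.sort(key=lambda s: (s.chrom, s.start, s.end))

    # -- GRO-seq-like coverage
    intensities = sim._gro_intensities(genes, response_map)
    pre_plus, pre_minus = sim._sample_condition_reads(genes, intensities, "pre")
    post_plus, post_minus = sim._sample_condition_reads(genes, intensities, "post")

    # -- active-promoter histone-marker peaks (near responsive TSSs)
    marker_peaks: list[GenomicInterval] = []
    for g in genes:
        if response_map[g.gene_id] == "nonresponsive":
            continue
        if rng.random() < 0.8:
            width = int(rng.integers(500, 1_501))
            center = g.tss + int(rng.integers(-500, 501))
            s = max(0, center - width // 2)
            marker_peaks.append(GenomicInterval(g.chrom, s, s + width))
    marker_peaks += sim._background_sites(cfg.er_background_per_bp)
    marker_peaks.sort(key=lambda s: (s.chrom, s.start, s.end))

    # -- truth from emitted geometry (independent brute-force scan)
    truth = _derive_truth(
        genes,
        response_map,
        pre_complexes,
        er_complexes,
        standalone_sites,
        er_true,
        intensities,
        cfg,
    )
    truth_cx = pd.DataFrame(
        [
            {
                "complex_id": cx.complex_id,
                "chrom": cx.chrom,
                "span_start": cx.span[0],
                "span_end": cx.span[1],
                "n_anchors": len(cx.anchors),
                "gene_id": cx.gene_id or ".",
                "response": cx.response or ".",
                "intended_category": cx.intended_category or ".",
                "disrupted": "." if cx.disrupted is None else str(cx.disrupted),
                "outcome": cx.outcome or ".",
            }
            for cx in pre_complexes
        ]
    )

    # -- write bundle
    files: dict[str, Path] = {}

    def _path(name: str) -> Path:
        p = out / name
        files[name.split(".")[0]] = p
        return p

    write_genes(genes, _path("genes.tsv"))
    with open(_path("response.tsv"), "w") as fh:
        fh.write("gene_id\tlabel\n")
        for r in response:
            fh.write(f"{r.gene_id}\t{r.label}\n")
    write_interactions(
        [p for cx in pre_complexes for p in sim._chain_pairs(cx, rng)],
        _path("polII_pre.bedpe"),
    )
    write_interactions(
        [p for cx in er_complexes for p in sim._chain_pairs(cx, rng)],
        _path("er_post.bedpe"),
    )
    write_bed(er_true, _path("er_sites_pre_truth.bed"))
    for i, st in enumerate(studies, start=1):
        write_bed(st, _path(f"er_pre_study{i}.bed"))
    for factor, peaks in pioneers.items():
        write_bed(peaks, _path(f"{factor}.bed"))
    write_bed(standalone_sites, _path("standalone_post.bed"))
    write_bed(marker_peaks, _path("h3k4me3.bed"))
    write_bedgraph(pre_plus, _path("gro_pre_plus.bedGraph"))
    write_bedgraph(pre_minus, _path("gro_pre_minus.bedGraph"))
    write_bedgraph(post_plus, _path("gro_post_plus.bedGraph"))
    write_bedgraph(post_minus, _path("gro_post_minus.bedGraph"))
    truth.to_csv(_path("truth.tsv"), sep="\t", index=False)
    truth_cx.to_csv(_path("truth_complexes.tsv"), sep="\t", index=False)
    with open(_path("chrom.sizes"), "w") as fh:
        for c in sim.chroms:
            fh.write(f"{c}\t{cfg.chrom_length}\n")
    with open(_path("sim_config.yaml"), "w") as fh:
        echo = asdict(cfg)
        echo["class_counts"] = list(cfg.class_counts) if cfg.class_counts else None
        yaml.safe_dump(echo, fh, sort_keys=True)

    return SimResult(
        config=cfg,
        out_dir=out,
        files=files,
        genes=genes,
        response=response,
        truth=truth,
        truth_complexes=truth_cx,
        chrom_sizes=dict(sim.sizes),
        library_sizes={
            "pre": pre_plus.library_size,
            "post": post_plus.library_size,
        },
    )


def _derive_truth(
    genes,
    response_map,
    pre_complexes,
    er_complexes,
    standalone_sites,
    er_true_sites,
    intensities,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Brute-force truth labels from the emitted geometry.

    Deliberately simple linear scans, independent of the pipeline's
    indexed implementations, so that pipeline-vs-truth agreement is a
    real check and not a tautology.
    """
    lam = {r["gene_id"]: r for r in intensities}
    own_complex = {cx.gene_id: cx for cx in pre_complexes if cx.gene_id}
    rows = []
    for g in genes:
        pre_cat, pre_cx = _scan_category(g, pre_complexes, cfg.anchor_window)
        transition = "."
        disrupted = "."
        if pre_cat == "anchor" and response_map[g.gene_id] != "nonresponsive":
            post_cat, _ = _scan_category(g, er_complexes, cfg.anchor_window)
            if post_cat == "outside":
                near_standalone = any(
                    s.chrom == g.chrom
                    and _point_interval_dist(g.tss, s.start, s.end) <= cfg.standalone_window
                    for s in standalone_sites
                )
                post_cat = "stand-alone" if near_standalone else "none"
            transition = f"anchor-to-{post_cat}"
            disrupted = str(transition != "anchor-to-anchor")
        own = own_complex.get(g.gene_id)
        had_er = False
        if own is not None:
            had_er = any(
                s.chrom == own.chrom
                and any(s.start < a.end and a.start < s.end for a in own.anchors)
                for s in er_true_sites
            )
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "response": response_map[g.gene_id],
                "pre_category": pre_cat,
                "pre_complex_id": pre_cx or ".",
                "transition": transition,
                "disrupted": disrupted,
                "had_er_in_anchor": str(had_er),
                "pause_ratio_pre": lam[g.gene_id]["pr_pre"],
                "pause_ratio_post": lam[g.gene_id]["pr_post"],
            }
        )
    return pd.DataFrame(rows)


def _scan_category(gene: Gene, complexes, anchor_window: int):
    best = (anchor_window + 1, None)
    covering = None
    for cx in complexes:
        if cx.chrom != gene.chrom:
            continue
        for a in cx.anchors:
            d = _point_interval_dist(gene.tss, a.start, a.end)
            if d < best[0]:
                best = (d, cx.complex_id)
        lo, hi = cx.span
        if lo <= gene.tss < hi and covering is None:
            covering = cx.complex_id
    if best[1] is not None:
        return "anchor", best[1]
    if covering is not None:
        return "loop", covering
    return "outside", None


def truth_compare(
    truth: pd.DataFrame,
    annotations=None,
    transition_records=None,
    pause_estimates: dict[str, float] | None = None,
    consensus_sites=None,
    true_sites=None,
) -> dict:
    """Score pipeline outputs against the generator's truth table.

    Returns per-stage agreement: category accuracy, transition confusion
    counts, disrupted-fraction error per class, Spearman correlation of
    pause-ratio estimates, and consensus precision/recall vs true sites.
    Raises on gene-id mismatches.
    """
    from scipy.stats import spearmanr

    report: dict = {}
    truth_ids = set(truth["gene_id"])
    if annotations is not None:
        ann_ids = {a.gene_id for a in annotations}
        if not ann_ids <= truth_ids:
            raise KeyError(f"annotated genes missing from truth: {sorted(ann_ids - truth_ids)[:5]}")
        cat = dict(zip(truth["gene_id"], truth["pre_category"]))
        agree = sum(1 for a in annotations if cat[a.gene_id] == a.category)
        report["category_accuracy"] = agree / len(annotations)
    if transition_records is not None:
        t_truth = dict(zip(truth["gene_id"], truth["transition"]))
        if any(r.gene_id not in truth_ids for r in transition_records):
            raise KeyError("transition record for unknown gene")
        confusion: dict[tuple[str, str], int] = {}
        agree = 0
        for r in transition_records:
            key = (t_truth[r.gene_id], r.transition)
            confusion[key] = confusion.get(key, 0) + 1
            agree += key[0] == key[1]
        report["transition_accuracy"] = agree / len(transition_records) if transition_records else None
        report["transition_confusion"] = confusion
        for cls in ("induced", "repressed"):
            recs = [r for r in transition_records if r.response == cls]
            if recs:
                est = sum(r.disrupted for r in recs) / len(recs)
                tr = truth[(truth["response"] == cls) & (truth["disrupted"] != ".")]
                tru = (tr["disrupted"] == "True").mean() if len(tr) else np.nan
                report[f"disrupted_fraction_{cls}"] = est
                report[f"disrupted_fraction_error_{cls}"] = abs(est - tru)
    if pause_estimates is not None:
        sub = truth[truth["gene_id"].isin(pause_estimates)]
        if len(sub) != len(pause_estimates):
            raise KeyError("pause estimates contain unknown genes")
        rho = spearmanr(
            sub["pause_ratio_pre"].to_numpy(),
            np.array([pause_estimates[g] for g in sub["gene_id"]]),
        ).statistic
        report["pause_ratio_spearman"] = float(rho)
    if consensus_sites is not None and true_sites is not None:
        pred = [c.interval for c in consensus_sites]
        tp_pred = sum(
            1
            for p in pred
            if any(p.chrom == t.chrom and p.start < t.end and t.start < p.end for t in true_sites)
        )
        tp_true = sum(
            1
            for t in true_sites
            if any(p.chrom == t.chrom and p.start < t.end and t.start < p.end for p in pred)
        )
        report["consensus_precision"] = tp_pred / len(pred) if pred else None
        report["consensus_recall"] = tp_true / len(true_sites) if true_sites else None
    return report
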