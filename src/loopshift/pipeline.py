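"""Config-driven end-to-end run over a (synthetic or user-supplied) bundle.

Stage order: simulate (optional) -> consensus cistrome -> complex assembly
-> gene annotation (pre and post) -> transition classification and
contingency -> pausing and condition comparisons -> metagene profile ->
permutation enrichment -> machine-readable report. Every table is TSV
with a comment header carrying seed and config hash; the report is
deterministic JSON (byte-identical under a fixed config and seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.proportion import proportion_confint

from . import simulate as sim_mod
from .cistrome import consensus_cistrome, cooccurrence_fraction
from .complexes import (
    AnnotationConfig,
    annotate_genes,
    assemble_complexes,
    complex_content,
)
from .core import GenomicInterval, IntervalIndex
from .enrichment import permutation_enrichment, promoter_marker_association
from .io import (
    read_bed,
    read_coverage,
    read_genes,
    read_interactions,
    read_response_table,
    write_table,
)
from .signal import ProfileConfig, compare_conditions, metagene_profile, pause_ratio
from .simulate import SimConfig, simulate, truth_compare
from .transitions import (
    classify_transitions,
    er_in_anchor_flag,
    filter_standalone_sites,
    transition_contingency,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    data_dir: str = "data"
    out_dir: str = "results"
    seed: int = 7
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    anchor_window: int = 5_000
    standalone_window: int = 20_000
    gro_flank: int = 1_000
    tss_window: int = 300
    min_gene_length: int = 2_000
    min_studies: int = 2
    n_perm: int = 200
    log_level: str = "INFO"

    KNOWN_KEYS = None  # filled below

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(self.anchor_window, self.standalone_window)

    def profile_config(self) -> ProfileConfig:
        return ProfileConfig(
            flank=self.gro_flank,
            tss_window=self.tss_window,
            min_gene_length=self.min_gene_length,
        )


RunConfig.KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)} - {"KNOWN_KEYS"}

_FIELD_TYPES = {
    "data_dir": str,
    "out_dir": str,
    "seed": int,
    "simulate": bool,
    "sim_overrides": dict,
    "anchor_window": int,
    "standalone_window": int,
    "gro_flank": int,
    "tss_window": int,
    "min_gene_length": int,
    "min_studies": int,
    "n_perm": int,
    "log_level": str,
}


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Schema-check a YAML run config; returns (config-or-None, error list)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config must be a YAML mapping"]
    for key in raw:
        if key not in RunConfig.KNOWN_KEYS:
            errors.append(f"unknown key: {key}")
    for key, val in raw.items():
        want = _FIELD_TYPES.get(key)
        if want is not None and not isinstance(val, want):
            errors.append(f"key {key}: expected {want.__name__}, got {type(val).__name__}")
    if not raw.get("simulate", True) and "data_dir" not in raw:
        errors.append("missing required key: data_dir (when simulate is false)")
    if errors:
        return None, errors
    return RunConfig(**raw), []


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"stage {stage}: required input {path} is missing")
    return path


def _binomial_ci(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, alpha=0.05, method="normal")
    return (float(lo), float(hi))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; writes TSV intermediates and report.json."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann_cfg = config.annotation_config()
    prof_cfg = config.profile_config()
    report: dict = {"seed": config.seed}

    if config.simulate:
        sim_cfg = SimConfig(seed=config.seed, **config.sim_overrides)
        sim = simulate(sim_cfg, data)
        truth = sim.truth
    else:
        truth = None

    # -- inputs
    gene_set = read_genes(_require(data / "genes.tsv", "read_genes"))
    genes = gene_set.genes
    response = {r.gene_id: r.label for r in read_response_table(_require(data / "response.tsv", "response"))}
    report["n_genes"] = len(genes)
    report["n_genes_dropped_multi_tss"] = gene_set.n_dropped_multi_tss
    report["response_counts"] = {
        lab: sum(1 for v in response.values() if v == lab)
        for lab in ("induced", "repressed", "nonresponsive")
    }
    chrom_sizes = {}
    for line in open(_require(data / "chrom.sizes", "chrom_sizes")):
        c, s = line.split()
        chrom_sizes[c] = int(s)

    # -- consensus ER cistrome from pseudo-studies
    study_paths = sorted(data.glob("er_pre_study*.bed"))
    studies = [read_bed(p) for p in study_paths]
    consensus = consensus_cistrome(studies, min_studies=config.min_studies)
    er_sites = [c.interval for c in consensus]
    write_table(
        pd.DataFrame(
            {
                "chrom": [s.interval.chrom for s in consensus],
                "start": [s.interval.start for s in consensus],
                "end": [s.interval.end for s in consensus],
                "support": [s.support for s in consensus],
            }
        ),
        out / "consensus_er_sites.tsv",
        seed=config.seed,
        config=config,
    )
    report["n_consensus_er_sites"] = len(consensus)

    # -- complexes and gene categories, pre and post
    polII_pairs = read_interactions(_require(data / "polII_pre.bedpe", "complexes"))
    polII_complexes = assemble_complexes(polII_pairs)
    er_pairs = read_interactions(_require(data / "er_post.bedpe", "complexes"))
    er_complexes = assemble_complexes(er_pairs)
    pre_annot = annotate_genes(genes, polII_complexes, ann_cfg, condition="pre")
    post_annot = annotate_genes(genes, er_complexes, ann_cfg, condition="post")
    report["n_polII_complexes"] = len(polII_complexes)
    report["n_er_complexes"] = len(er_complexes)
    cat_counts: dict[str, dict[str, int]] = {}
    for a in pre_annot:
        lab = response.get(a.gene_id, "nonresponsive")
        cat_counts.setdefault(lab, {"anchor": 0, "loop": 0, "outside": 0})
        cat_counts[lab][a.category] += 1
    report["pre_category_counts"] = cat_counts
    write_table(
        pd.DataFrame(
            {
                "gene_id": [a.gene_id for a in pre_annot],
                "pre_category": [a.category for a in pre_annot],
                "pre_complex": [a.complex_id or "." for a in pre_annot],
                "post_category": [a.category for a in post_annot],
                "post_complex": [a.complex_id or "." for a in post_annot],
            }
        ),
        out / "gene_annotations.tsv",
        seed=config.seed,
        config=config,
    )

    # -- complex content and pioneer co-occurrence
    pioneer_sets = {p.stem: read_bed(p) for p in sorted(data.glob("*.bed")) if p.stem in ("foxa1", "gata3")}
    responsive_cx_ids = {
        a.complex_id for a in pre_annot
        if a.category == "anchor" and response.get(a.gene_id) in ("induced", "repressed")
    }
    responsive_cx = [c for c in polII_complexes if c.complex_id in responsive_cx_ids]
    _, content = complex_content(
        responsive_cx, {"er": er_sites, **{k: list(v) for k, v in pioneer_sets.items()}}
    )
    report["complex_content"] = {
        s.factor: {
            "n_with_site": s.n_with_site,
            "fraction_with_site": s.fraction_with_site,
            "mean_sites_among_positive": s.mean_sites_among_positive,
        }
        for s in content
    }
    if pioneer_sets:
        cooc = cooccurrence_fraction(
            er_sites,
            list(pioneer_sets.values()),
            within=[c.span for c in responsive_cx],
        )
        report["er_pioneer_cooccurrence"] = {
            "n_overlapping": cooc.n_overlapping,
            "n_total": cooc.n_total,
            "fraction": cooc.fraction,
        }

    # -- transitions and disruption inference
    standalone_raw = read_bed(_require(data / "standalone_post.bed", "transitions"))
    standalone = filter_standalone_sites(list(standalone_raw), er_complexes)
    er_site_idx = IntervalIndex(er_sites)
    cx_by_id = {c.complex_id: c for c in polII_complexes}
    gene_by_id = {g.gene_id: g for g in genes}
    flags = {
        a.gene_id: er_in_anchor_flag(
            gene_by_id[a.gene_id], cx_by_id[a.complex_id], er_site_idx
        )
        for a in pre_annot
        if a.category == "anchor" and a.complex_id in cx_by_id
        and response.get(a.gene_id) in ("induced", "repressed")
    }
    records = classify_transitions(
        genes, response, pre_annot, post_annot, standalone, ann_cfg, er_in_anchor_flags=flags
    )
    responsive_records = [r for r in records if r.response in ("induced", "repressed")]
    trans_counts: dict[str, dict[str, int]] = {}
    for r in responsive_records:
        trans_counts.setdefault(r.response, {})
        trans_counts[r.response][r.transition] = trans_counts[r.response].get(r.transition, 0) + 1
    report["transition_counts"] = trans_counts
    disrupted = {}
    for cls in ("induced", "repressed"):
        recs = [r for r in responsive_records if r.response == cls]
        k = sum(r.disrupted for r in recs)
        lo, hi = _binomial_ci(k, len(recs))
        disrupted[cls] = {
            "n": len(recs),
            "n_disrupted": k,
            "fraction": (k / len(recs)) if recs else None,
            "ci95": [lo, hi],
        }
    report["disrupted"] = disrupted
    chi = transition_contingency(responsive_records, collapse_to_disruption=True)
    report["chi_squared"] = {
        "table": chi.table,
        "statistic": chi.statistic,
        "df": chi.df,
        "p_value": chi.p_value,
    }
    write_table(
        pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in responsive_records],
                "response": [r.response for r in responsive_records],
                "transition": [r.transition for r in responsive_records],
                "disrupted": [r.disrupted for r in responsive_records],
                "had_er_in_anchor_before": [r.had_er_in_anchor_before for r in responsive_records],
            }
        ),
        out / "transitions.tsv",
        seed=config.seed,
        config=config,
    )

    # -- GRO-seq pausing, pre vs post
    pre_tracks = read_coverage(
        _require(data / "gro_pre_plus.bedGraph", "pausing"),
        _require(data / "gro_pre_minus.bedGraph", "pausing"),
        condition="pre",
    )
    post_tracks = read_coverage(
        _require(data / "gro_post_plus.bedGraph", "pausing"),
        _require(data / "gro_post_minus.bedGraph", "pausing"),
        condition="post",
    )
    pause = {"pre": [], "post": []}
    for cond, (plus, minus) in (("pre", pre_tracks), ("post", post_tracks)):
        for g in genes:
            ps = pause_ratio(g, plus, minus, prof_cfg, condition=cond)
            if ps is not None:
                pause[cond].append(ps)
    pause_summary = {}
    for cls in ("induced", "repressed"):
        ids = {g for g, lab in response.items() if lab == cls}
        before = [s for s in pause["pre"] if s.gene_id in ids]
        after = [s for s in pause["post"] if s.gene_id in ids]
        entry = {}
        for metric in ("pause_ratio", "body_density", "tss_density", "antisense_tss_rpm"):
            cmp = compare_conditions(before, after, metric=metric, paired=True)
            entry[metric] = {
                "median_pre": cmp.median_before,
                "median_post": cmp.median_after,
                "direction": cmp.direction,
                "t": None if np.isinf(cmp.test.statistic) else cmp.test.statistic,
                "p": cmp.test.p_value,
                "n": cmp.n_genes,
            }
        pause_summary[cls] = entry
    report["pausing"] = pause_summary
    write_table(
        pd.DataFrame(
            [
                {
                    "gene_id": s.gene_id,
                    "condition": s.condition,
                    "tss_density": s.tss_density,
                    "body_density": s.body_density,
                    "pause_ratio": s.pause_ratio,
                    "antisense_tss_rpm": s.antisense_tss_rpm,
                }
                for cond in ("pre", "post")
                for s in pause[cond]
            ]
        ),
        out / "pause_stats.tsv",
        seed=config.seed,
        config=config,
    )

    # -- metagene (GRO-seq, sense strand, pre-treatment, responsive genes)
    responsive_genes = [g for g in genes if response.get(g.gene_id) in ("induced", "repressed")]
    profile = metagene_profile(responsive_genes, pre_tracks, prof_cfg, strand_mode="sense")
    prof_rows = (
        [
            {"segment": "promoter", "index": i, "rpm": v}
            for i, v in enumerate(profile.promoter)
        ]
        + [{"segment": "body", "index": i, "rpm": v} for i, v in enumerate(profile.body)]
        + [{"segment": "tes", "index": i, "rpm": v} for i, v in enumerate(profile.tes)]
    )
    write_table(pd.DataFrame(prof_rows), out / "metagene_pre_sense.tsv", seed=config.seed, config=config)
    report["metagene"] = {
        "n_genes": profile.n_genes,
        "n_skipped_short": profile.n_skipped_short,
        "promoter_peak_rpm": float(profile.promoter.max()),
        "body_mean_rpm": float(profile.body.mean()),
    }

    # -- enrichment: ER sites in Pol II complexes; pioneer peaks near promoters
    enr = permutation_enrichment(
        er_sites,
        [c.span for c in polII_complexes],
        statistic="jaccard",
        n_perm=config.n_perm,
        alternative="greater",
        seed=config.seed,
        chrom_sizes=chrom_sizes,
    )
    report["enrichment"] = {
        "er_in_polII_complexes": {
            "statistic": "jaccard",
            "observed": enr.observed,
            "p_value": enr.p_value,
            "n_perm": enr.n_perm,
        }
    }
    marker_path = data / "h3k4me3.bed"
    marker_name, marker_peaks = None, None
    if marker_path.exists():
        marker_name, marker_peaks = "h3k4me3", list(read_bed(marker_path))
    elif pioneer_sets:
        marker_name = sorted(pioneer_sets)[0]
        marker_peaks = list(pioneer_sets[marker_name])
    if marker_peaks:
        assoc = promoter_marker_association(
            responsive_genes,
            marker_peaks,
            n_perm=config.n_perm,
            seed=config.seed,
            chrom_sizes=chrom_sizes,
        )
        report["enrichment"][f"{marker_name}_near_promoters"] = {
            "statistic": assoc.statistic_name,
            "observed": assoc.observed,
            "p_value": assoc.p_value,
            "n_perm": assoc.n_perm,
        }

    # -- truth recovery (synthetic runs only)
    if truth is not None:
        pause_est = {
            s.gene_id: s.pause_ratio for s in pause["pre"] if s.pause_ratio is not None
        }
        true_sites = list(read_bed(data / "er_sites_pre_truth.bed"))
        scores = truth_compare(
            truth,
            annotations=pre_annot,
            transition_records=responsive_records,
            pause_estimates=pause_est,
            consensus_sites=consensus,
            true_sites=true_sites,
        )
        scores.pop("transition_confusion", None)
        report["truth_recovery"] = scores

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return report
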