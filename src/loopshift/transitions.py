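"""Chromatin-reconfiguration inference from pre/post complex annotations.

Genes anchored in Pol II complexes before treatment are re-examined
against ERα complexes after treatment. Each pre-treatment anchor gene
gets one of four transitions:

* ``anchor-to-anchor``     — still within the anchor window of an ERα anchor;
* ``anchor-to-loop``       — TSS inside an ERα complex span but off-anchor;
* ``anchor-to-stand-alone``— near (default +/-20 kb) a non-interacting
  ERα binding site only;
* ``anchor-to-none``       — none of the above.

Disruption of the original complex is *inferred*, not observed: every
transition other than anchor-to-anchor counts as disrupted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .complexes import (
    AnnotationConfig,
    ChromatinComplex,
    GeneComplexAnnotation,
    assign_standalone,
)
from .core import Gene, GenomicInterval, IntervalIndex

TRANSITIONS = (
    "anchor-to-anchor",
    "anchor-to-loop",
    "anchor-to-stand-alone",
    "anchor-to-none",
)


@dataclass(frozen=True)
class TransitionRecord:
    gene_id: str
    response: str
    before_category: str
    after_category: str  # anchor | loop | stand-alone | none
    transition: str
    disrupted: bool
    had_er_in_anchor_before: bool = False


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    paired: bool
    degenerate: bool = False  # zero-variance input handled by convention


def filter_standalone_sites(
    sites: Sequence[GenomicInterval], er_complexes: Sequence[ChromatinComplex]
) -> list[GenomicInterval]:
    """Binding sites not overlapping any ERα complex anchor (stand-alone events)."""
    anchor_idx = IntervalIndex([a for cx in er_complexes for a in cx.anchors])
    return [s for s in sites if not anchor_idx.overlaps_any(s)]


def classify_transitions(
    genes: Sequence[Gene],
    response: Mapping[str, str],
    polII_annotations: Sequence[GeneComplexAnnotation],
    er_annotations: Sequence[GeneComplexAnnotation],
    standalone_sites: Sequence[GenomicInterval],
    config: AnnotationConfig = AnnotationConfig(),
    er_in_anchor_flags: Mapping[str, bool] | None = None,
) -> list[TransitionRecord]:
    """Transition of every pre-treatment (Pol II) anchor gene.

    ``er_annotations`` must come from post-treatment complexes;
    ``standalone_sites`` are post-treatment binding sites external to any
    ERα complex anchor.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    er_by_id = {a.gene_id: a for a in er_annotations}
    standalone_idx = IntervalIndex(list(standalone_sites))
    records: list[TransitionRecord] = []
    for before in polII_annotations:
        if before.gene_id not in gene_by_id:
            raise KeyError(f"annotated gene {before.gene_id} missing from gene list")
        if before.category != "anchor":
            continue
        gene = gene_by_id[before.gene_id]
        after = er_by_id.get(before.gene_id)
        if after is not None and after.category == "anchor":
            after_cat = "anchor"
        elif after is not None and after.category == "loop":
            after_cat = "loop"
        elif assign_standalone(gene, standalone_idx, config):
            after_cat = "stand-alone"
        else:
            after_cat = "none"
        transition = f"anchor-to-{after_cat}"
        records.append(
            TransitionRecord(
                gene_id=gene.gene_id,
                response=response.get(gene.gene_id, "nonresponsive"),
                before_category="anchor",
                after_category=after_cat,
                transition=transition,
                disrupted=(transition != "anchor-to-anchor"),
                had_er_in_anchor_before=(
                    bool(er_in_anchor_flags.get(gene.gene_id, False))
                    if er_in_anchor_flags
                    else False
                ),
            )
        )
    return records


def er_in_anchor_flag(
    gene: Gene,
    polII_complex: ChromatinComplex,
    er_sites_pre: IntervalIndex | Sequence[GenomicInterval],
) -> bool:
    """True iff a pre-treatment ERα site overlaps any anchor of the gene's complex."""
    idx = (
        er_sites_pre
        if isinstance(er_sites_pre, IntervalIndex)
        else IntervalIndex(list(er_sites_pre))
    )
    return any(idx.overlaps_any(a) for a in polII_complex.anchors)


def transition_contingency(
    records: Sequence[TransitionRecord],
    collapse_to_disruption: bool = True,
) -> ContingencyResult:
    """Chi-squared homogeneity test of transition distributions across classes.

    Builds an induced/repressed x transition-category table (or the
    collapsed 2x2 disrupted/retained table) and applies the Pearson
    chi-squared test (no continuity correction).
    """
    classes = sorted({r.response for r in records if r.response != "nonresponsive"})
    if len(classes) < 2:
        raise ValueError("need >=2 response classes for a contingency test")
    if collapse_to_disruption:
        cols = ["disrupted", "retained"]
        table = [
            [
                sum(1 for r in records if r.response == c and r.disrupted),
                sum(1 for r in records if r.response == c and not r.disrupted),
            ]
            for c in classes
        ]
    else:
        present = [t for t in TRANSITIONS if any(r.transition == t for r in records)]
        cols = present
        table = [
            [sum(1 for r in records if r.response == c and r.transition == t) for t in present]
            for c in classes
        ]
    return chi_squared_table(table)


def chi_squared_table(table) -> ContingencyResult:
    """Pearson chi-squared on a 2d count table; errors on zero expected cells."""
    arr = np.asarray(table, dtype=float)
    expected = stats.contingency.expected_freq(arr)
    if np.any(expected == 0):
        raise ValueError(
            "expected cell count of zero; collapse categories or use an exact test"
        )
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return ContingencyResult(
        table=tuple(tuple(int(x) for x in row) for row in arr),
        statistic=float(stat),
        df=int(df),
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
    )


def group_mean_test(
    values_a: Sequence[float], values_b: Sequence[float], paired: bool = False
) -> TTestResult:
    """Two-sided t test: Welch for unpaired groups, one-sample-on-differences
    for paired groups. Zero-variance inputs are resolved by convention
    (equal constants -> p=1; constant nonzero paired shift -> p=0, flagged)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired and a.shape != b.shape:
        raise ValueError("paired test requires equal-length groups")
    if min(a.size, b.size) < 2:
        raise ValueError("need n >= 2 per group")
    if paired:
        diff = a - b
        if np.all(diff == diff[0]):
            if diff[0] == 0:
                return TTestResult(0.0, 1.0, True, degenerate=True)
            return TTestResult(np.sign(diff[0]) * np.inf, 0.0, True, degenerate=True)
        t, p = stats.ttest_rel(a, b)
        return TTestResult(float(t), float(p), True)
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, False, degenerate=True)
        return TTestResult(np.sign(a.mean() - b.mean()) * np.inf, 0.0, False, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t), float(p), False)
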