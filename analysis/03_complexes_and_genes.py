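"""Assemble chromatin complexes and categorize genes against them.

Pol II interaction pairs (pre-treatment) become complexes; every gene is
an anchor gene (TSS within +/-5 kb of an anchor region), a loop gene
(TSS inside the complex span), or outside. Complex content is tallied
for the consensus ERα sites and the pioneer factors.
"""

import pandas as pd

from loopshift.cistrome import cooccurrence_fraction
from loopshift.core import GenomicInterval
from loopshift.io import read_bed, write_table
from loopshift.complexes import complex_content

from _shared import DATA, OUT, SEED, load_annotated, load_response

complexes, annotations = load_annotated("pre")
response = load_response()

cons = pd.read_csv(OUT / "consensus_er_sites.tsv", sep="\t", comment="#")
er_sites = [
    GenomicInterval(r.chrom, r.start, r.end) for r in cons.itertuples()
]
pioneers = {name: read_bed(DATA / f"{name}.bed") for name in ("foxa1", "gata3")}

counts: dict[str, dict[str, int]] = {}
for a in annotations:
    lab = response.get(a.gene_id, "nonresponsive")
    counts.setdefault(lab, {"anchor": 0, "loop": 0, "outside": 0})
    counts[lab][a.category] += 1

responsive_ids = {
    a.complex_id
    for a in annotations
    if a.category == "anchor" and response.get(a.gene_id) in ("induced", "repressed")
}
responsive_cx = [c for c in complexes if c.complex_id in responsive_ids]
_, content = complex_content(
    responsive_cx, {"er": er_sites, **{k: list(v) for k, v in pioneers.items()}}
)
cooc = cooccurrence_fraction(
    er_sites, list(pioneers.values()), within=[c.span for c in responsive_cx]
)

write_table(
    pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in annotations],
            "response": [response.get(a.gene_id, "nonresponsive") for a in annotations],
            "category": [a.category for a in annotations],
            "complex_id": [a.complex_id or "." for a in annotations],
            "distance_to_nearest_anchor": [a.distance_to_nearest_anchor for a in annotations],
        }
    ),
    OUT / "gene_categories_pre.tsv",
    seed=SEED,
)

print(f"Pol II complexes: {len(complexes)} "
      f"({len(responsive_cx)} containing a responsive anchor gene)")
for lab, c in sorted(counts.items()):
    print(f"  {lab}: {c}")
for s in content:
    print(
        f"  complexes with {s.factor} in anchors: {s.n_with_site}/{s.n_complexes} "
        f"({100 * s.fraction_with_site:.0f}%), "
        f"mean sites among positive: {s.mean_sites_among_positive:.1f}"
    )
print(
    f"ERα sites co-occurring with a pioneer inside responsive complexes: "
    f"{cooc.n_overlapping}/{cooc.n_total} ({100 * cooc.fraction:.0f}%)"
)
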