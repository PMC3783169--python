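"""Infer chromatin reconfiguration from pre/post complex annotations.

Every gene anchored in a Pol II complex before treatment is classified
against the post-treatment ERα complexes (anchor-to-anchor / loop /
stand-alone / none); any transition away from an anchor is read as
disruption of the original complex. The induced and repressed
distributions are compared with a chi-squared homogeneity test.
"""

import pandas as pd

from loopshift.io import read_bed, write_table
from loopshift.transitions import (
    classify_transitions,
    filter_standalone_sites,
    transition_contingency,
)

from _shared import ANNOT, DATA, OUT, SEED, load_annotated, load_genes, load_response

genes = load_genes()
response = load_response()
_, pre_annot = load_annotated("pre")
er_complexes, post_annot = load_annotated("post")

standalone = filter_standalone_sites(
    list(read_bed(DATA / "standalone_post.bed")), er_complexes
)
records = [
    r
    for r in classify_transitions(genes, response, pre_annot, post_annot, standalone, ANNOT)
    if r.response in ("induced", "repressed")
]
chi = transition_contingency(records, collapse_to_disruption=True)

write_table(
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "response": [r.response for r in records],
            "transition": [r.transition for r in records],
            "disrupted": [r.disrupted for r in records],
        }
    ),
    OUT / "transitions.tsv",
    seed=SEED,
)

for cls in ("repressed", "induced"):
    sub = [r for r in records if r.response == cls]
    k = sum(r.disrupted for r in sub)
    dist = pd.Series([r.transition for r in sub]).value_counts().to_dict()
    print(f"{cls}: {k}/{len(sub)} disrupted ({100 * k / len(sub):.0f}%)  {dist}")
print(
    f"chi-squared (disrupted/retained x class): "
    f"stat {chi.statistic:.1f}, df {chi.df}, p {chi.p_value:.2e}"
)
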