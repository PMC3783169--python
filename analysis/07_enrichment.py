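"""Permutation tests of spatial association.

Jaccard enrichment of consensus ERα sites inside Pol II complex spans,
and promoter proximity of pioneer-factor peaks, both against a null that
relocates intervals uniformly within their chromosomes (lengths kept).
"""

import pandas as pd

from loopshift.core import GenomicInterval
from loopshift.enrichment import permutation_enrichment, promoter_marker_association
from loopshift.io import read_bed

from _shared import DATA, OUT, SEED, load_annotated, load_chrom_sizes, load_genes, load_response

chrom_sizes = load_chrom_sizes()
complexes, _ = load_annotated("pre")
cons = pd.read_csv(OUT / "consensus_er_sites.tsv", sep="\t", comment="#")
er_sites = [GenomicInterval(r.chrom, r.start, r.end) for r in cons.itertuples()]

enr = permutation_enrichment(
    er_sites,
    [c.span for c in complexes],
    statistic="jaccard",
    n_perm=500,
    alternative="greater",
    seed=SEED,
    chrom_sizes=chrom_sizes,
)
print(
    f"ERα sites in Pol II complexes: Jaccard {enr.observed:.4f}, "
    f"null mean {enr.null_values.mean():.4f}, p = {enr.p_value:.4g} "
    f"(n_perm={enr.n_perm})"
)

response = load_response()
responsive = [g for g in load_genes() if response.get(g.gene_id) in ("induced", "repressed")]
for marker in ("h3k4me3", "foxa1"):
    peaks = list(read_bed(DATA / f"{marker}.bed"))
    assoc = promoter_marker_association(
        responsive, peaks, n_perm=500, seed=SEED, chrom_sizes=chrom_sizes
    )
    print(
        f"{marker} peaks near responsive promoters: mean nearest distance "
        f"{assoc.observed:.0f} bp, p = {assoc.p_value:.4g} (n_perm={assoc.n_perm})"
    )
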