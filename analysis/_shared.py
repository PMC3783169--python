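"""Paths, seed and loaders shared by the numbered analysis scripts.

All scripts run from the repository root and read the bundle written by
01_simulate.py into results/data/.
"""

from pathlib import Path

from loopshift.complexes import AnnotationConfig, annotate_genes, assemble_complexes
from loopshift.io import read_genes, read_interactions, read_response_table

SEED = 7
DATA = Path("results/data")
OUT = Path("results")

ANNOT = AnnotationConfig()  # +/-5 kb anchor window, +/-20 kb stand-alone window


def load_genes():
    return read_genes(DATA / "genes.tsv").genes


def load_response():
    return {r.gene_id: r.label for r in read_response_table(DATA / "response.tsv")}


def load_chrom_sizes():
    return {
        line.split()[0]: int(line.split()[1])
        for line in open(DATA / "chrom.sizes")
    }


def load_annotated(condition: str):
    """(complexes, per-gene annotations) for 'pre' (Pol II) or 'post' (ERα)."""
    bedpe = DATA / ("polII_pre.bedpe" if condition == "pre" else "er_post.bedpe")
    complexes = assemble_complexes(read_interactions(bedpe))
    annotations = annotate_genes(load_genes(), complexes, ANNOT, condition=condition)
    return complexes, annotations
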