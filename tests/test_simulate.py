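"""Synthetic-study generator: determinism, constructive consistency, truth scoring."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from loopshift.complexes import AnnotationConfig, annotate_genes, assemble_complexes
from loopshift.core import GenomicInterval
from loopshift.io import read_bed, read_coverage, read_genes, read_interactions
from loopshift.simulate import SimConfig, simulate, truth_compare

SMALL = dict(
    n_genes=100,
    n_background_complexes=20,
    reads_per_library=100_000,
    n_chromosomes=2,
    chrom_length=3_000_000,
)


@pytest.fixture(scope="module")
def small_sim(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return simulate(SimConfig(seed=5, **SMALL), out)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=9, **SMALL)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate(cfg, a)
        simulate(cfg, b)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        for name in names:
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        simulate(SimConfig(seed=1, **SMALL), tmp_path / "a")
        simulate(SimConfig(seed=2, **SMALL), tmp_path / "b")
        assert not filecmp.cmp(
            tmp_path / "a" / "genes.tsv", tmp_path / "b" / "genes.tsv", shallow=False
        )


class TestConstructiveConsistency:
    def test_anchor_truth_genes_have_nearby_emitted_anchor(self, small_sim):
        pairs = read_interactions(small_sim.files["polII_pre"])
        anchors = [p.anchor_a for p in pairs] + [p.anchor_b for p in pairs]
        truth = small_sim.truth
        genes = {g.gene_id: g for g in small_sim.genes}
        for _, row in truth[truth["pre_category"] == "anchor"].iterrows():
            g = genes[row["gene_id"]]
            best = min(
                (
                    0
                    if a.start <= g.tss < a.end
                    else min(abs(g.tss - a.start), abs(g.tss - (a.end - 1)))
                )
                for a in anchors
                if a.chrom == g.chrom
            )
            assert best <= small_sim.config.anchor_window

    def test_standalone_transition_genes_have_nearby_site(self, small_sim):
        sites = list(read_bed(small_sim.files["standalone_post"]))
        truth = small_sim.truth
        genes = {g.gene_id: g for g in small_sim.genes}
        rows = truth[truth["transition"] == "anchor-to-stand-alone"]
        for _, row in rows.iterrows():
            g = genes[row["gene_id"]]
            dists = [
                0
                if s.start <= g.tss < s.end
                else min(abs(g.tss - s.start), abs(g.tss - (s.end - 1)))
                for s in sites
                if s.chrom == g.chrom
            ]
            assert min(dists) <= small_sim.config.standalone_window

    def test_library_size_equals_emitted_reads(self, small_sim):
        for cond in ("pre", "post"):
            plus, minus = read_coverage(
                small_sim.files[f"gro_{cond}_plus"], small_sim.files[f"gro_{cond}_minus"]
            )
            assert plus.total_count + minus.total_count == small_sim.library_sizes[cond]

    def test_emitted_genes_parse_as_single_tss(self, small_sim):
        gs = read_genes(small_sim.files["genes"])
        assert len(gs) == len(small_sim.genes) and gs.n_dropped_multi_tss == 0


class TestNoiselessAgreement:
    def test_pipeline_annotation_reproduces_truth(self, tmp_path):
        cfg = SimConfig(
            seed=3, p_tss_in_anchor=1.0, study_dropout=0.0, study_jitter=0, **SMALL
        )
        res = simulate(cfg, tmp_path)
        complexes = assemble_complexes(read_interactions(res.files["polII_pre"]))
        anns = annotate_genes(res.genes, complexes, AnnotationConfig())
        truth_cat = dict(zip(res.truth["gene_id"], res.truth["pre_category"]))
        for a in anns:
            assert a.category == truth_cat[a.gene_id]


class TestTruthCompare:
    def test_noiseless_category_accuracy_is_one(self, small_sim):
        complexes = assemble_complexes(read_interactions(small_sim.files["polII_pre"]))
        anns = annotate_genes(small_sim.genes, complexes, AnnotationConfig())
        report = truth_compare(small_sim.truth, annotations=anns)
        assert report["category_accuracy"] == 1.0

    def test_shuffled_labels_score_at_chance(self, small_sim):
        complexes = assemble_complexes(read_interactions(small_sim.files["polII_pre"]))
        anns = annotate_genes(small_sim.genes, complexes, AnnotationConfig())
        rng = np.random.default_rng(0)
        shuffled = small_sim.truth.copy()
        shuffled["pre_category"] = rng.permutation(shuffled["pre_category"].to_numpy())
        report = truth_compare(shuffled, annotations=anns)
        # chance level for a 3-way label mix is well below perfect agreement
        assert report["category_accuracy"] < 0.8

    def test_unknown_gene_id_errors(self, small_sim):
        from loopshift.complexes import GeneComplexAnnotation

        bad = [GeneComplexAnnotation("nope", "pre", "anchor", "C0001", 0)]
        with pytest.raises(KeyError):
            truth_compare(small_sim.truth, annotations=bad)


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(d_repressed=1.5)

    def test_fraction_sum_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(frac_induced=0.7, frac_repressed=0.5)

    def test_class_counts_override(self):
        cfg = SimConfig(class_counts=(10, 20, 30))
        assert cfg.counts() == (10, 20, 30)
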