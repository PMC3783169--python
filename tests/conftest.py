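"""Shared fixtures and brute-force oracles.

The oracles here recompute interval operations by per-base boolean masks
or graph search on tiny chromosomes; they are deliberately independent of
the package's sweep/union-find implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from loopshift.core import GenomicInterval
from loopshift.pipeline import RunConfig, run_pipeline


def per_base_mask(intervals, chrom_len: int, chrom: str = "chr1") -> np.ndarray:
    """Boolean coverage mask of a single chromosome."""
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def mask_to_intervals(mask: np.ndarray, chrom: str = "chr1") -> list[GenomicInterval]:
    """Maximal runs of True as intervals."""
    out = []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def random_intervals(rng, n, chrom_len, max_len=2_000, chrom="chr1"):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, chrom_len - 1))
        length = int(rng.integers(1, min(max_len, chrom_len - start) + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Small end-to-end synthetic run shared across pipeline tests."""
    base = tmp_path_factory.mktemp("demo")
    cfg = RunConfig(
        data_dir=str(base / "data"),
        out_dir=str(base / "out"),
        seed=7,
        simulate=True,
        sim_overrides=dict(
            n_genes=150,
            n_background_complexes=40,
            reads_per_library=300_000,
            n_chromosomes=2,
            chrom_length=3_000_000,
        ),
        n_perm=50,
    )
    report = run_pipeline(cfg)
    return cfg, report


@pytest.fixture(scope="session")
def study_scale_run(tmp_path_factory):
    """Full-scale synthetic study mirroring the published class sizes.

    213 induced-gene and 144 repressed-gene complexes, every responsive
    TSS placed in an anchor, default read depth; used by the recovery
    checks on disruption fractions and pause ratios.
    """
    base = tmp_path_factory.mktemp("study")
    cfg = RunConfig(
        data_dir=str(base / "data"),
        out_dir=str(base / "out"),
        seed=7,
        simulate=True,
        sim_overrides=dict(class_counts=(213, 144, 443), p_tss_in_anchor=1.0),
        n_perm=200,
    )
    report = run_pipeline(cfg)
    return cfg, report
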