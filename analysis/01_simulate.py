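"""Generate the synthetic study bundle.

Emits genes, response labels, pre-treatment Pol II complexes, three noisy
ERα pseudo-studies plus pioneer-factor peaks, post-treatment ERα
complexes and stand-alone sites, and strand-specific GRO-seq-like
coverage for both conditions. Class sizes mirror the published study
(213 induced-gene and 144 repressed-gene complexes); every responsive
TSS is placed in an anchor so the disruption probabilities are
conditioned on exactly those complex counts.
"""

from loopshift.simulate import SimConfig, simulate

from _shared import DATA, SEED

cfg = SimConfig(seed=SEED, class_counts=(213, 144, 443), p_tss_in_anchor=1.0)
res = simulate(cfg, DATA)

counts = res.truth["response"].value_counts().to_dict()
print(f"wrote synthetic bundle to {DATA}")
print(f"genes: {len(res.genes)} ({counts})")
print(f"pre-treatment categories: {res.truth['pre_category'].value_counts().to_dict()}")
print(f"library sizes: {res.library_sizes}")
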