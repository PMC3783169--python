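"""Metagene profiles of nascent transcription for responsive genes.

Genes are aligned at TSS and TES with 1 kb per-bp flanks; variable-length
bodies are rescaled to 100 bins via natural cubic-spline interpolation at
1000 points. Profiles are written per strand mode (sense/antisense) and
condition, in RPM.
"""

import pandas as pd

from loopshift.io import read_coverage, write_table
from loopshift.signal import ProfileConfig, metagene_profile

from _shared import OUT, DATA, SEED, load_genes, load_response

genes = load_genes()
response = load_response()
responsive = [g for g in genes if response.get(g.gene_id) in ("induced", "repressed")]
cfg = ProfileConfig(flank=1_000)

rows = []
for cond in ("pre", "post"):
    tracks = read_coverage(
        DATA / f"gro_{cond}_plus.bedGraph", DATA / f"gro_{cond}_minus.bedGraph",
        condition=cond,
    )
    for mode in ("sense", "antisense"):
        prof = metagene_profile(responsive, tracks, cfg, strand_mode=mode)
        for segment, values in (
            ("promoter", prof.promoter),
            ("body", prof.body),
            ("tes", prof.tes),
        ):
            rows += [
                {
                    "condition": cond,
                    "strand_mode": mode,
                    "segment": segment,
                    "index": i,
                    "rpm": v,
                }
                for i, v in enumerate(values)
            ]
        print(
            f"{cond}/{mode}: {prof.n_genes} genes "
            f"({prof.n_skipped_short} too short), promoter peak "
            f"{prof.promoter.max():.3f} RPM, body mean {prof.body.mean():.3f} RPM"
        )

write_table(pd.DataFrame(rows), OUT / "metagene_profiles.tsv", seed=SEED)
print(f"wrote {OUT / 'metagene_profiles.tsv'}")
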