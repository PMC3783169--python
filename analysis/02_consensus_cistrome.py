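"""Build the consensus ERα cistrome from the three pseudo-studies.

Sites overlapping (>=1 bp, transitively clustered) in at least two
studies are kept as merged spans; the result is scored against the
generator's true site list.
"""

import pandas as pd

from loopshift.cistrome import consensus_cistrome
from loopshift.io import read_bed, write_table
from loopshift.simulate import truth_compare

from _shared import DATA, OUT, SEED

studies = [read_bed(p) for p in sorted(DATA.glob("er_pre_study*.bed"))]
consensus = consensus_cistrome(studies, min_studies=2)

truth = pd.read_csv(DATA / "truth.tsv", sep="\t")
true_sites = list(read_bed(DATA / "er_sites_pre_truth.bed"))
scores = truth_compare(truth, consensus_sites=consensus, true_sites=true_sites)

write_table(
    pd.DataFrame(
        {
            "chrom": [s.interval.chrom for s in consensus],
            "start": [s.interval.start for s in consensus],
            "end": [s.interval.end for s in consensus],
            "support": [s.support for s in consensus],
        }
    ),
    OUT / "consensus_er_sites.tsv",
    seed=SEED,
)

print(f"studies: {[len(s) for s in studies]} peaks each")
print(f"consensus sites (>=2 studies): {len(consensus)}")
print(
    f"vs true cistrome ({len(true_sites)} sites): "
    f"precision {scores['consensus_precision']:.3f}, "
    f"recall {scores['consensus_recall']:.3f}"
)
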