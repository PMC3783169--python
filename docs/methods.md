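# Methods

## Coordinates and windows

All coordinates are 0-based half-open (BED-native); refFlat-style inputs
are converted on read. The TSS of a minus-strand gene is `tx_end − 1`
(the first transcribed base), which makes every ±window rule symmetric
across strands. Point-to-interval distance is measured to the nearest
*contained* base, so a point one base past an interval end is at
distance 1, and "within ±W" rules are boundary-inclusive: a TSS exactly
5,000 bp from an anchor edge is an anchor gene. Chromosome names are
matched as exact strings; no silent "chr" normalization.

## Gene categorization and complex assembly

A chromatin complex is a connected component of the graph whose nodes
are the anchor regions of interaction pairs and whose edges are (a) the
pairs themselves and (b) ≥1 bp overlap between anchors; anchors of a
component are merged and the span runs from the first anchor start to
the last anchor end. This is the standard ChIA-PET cluster-to-complex
construction; it makes "multiple loops and anchor regions per complex"
well defined. Inter-chromosomal pairs are read but excluded from
assembly.

Categories are assigned with anchor precedence: **anchor** if the TSS is
within the anchor window (default 5 kb) of any anchor — ties across
complexes broken by smaller distance, then lexicographically smaller
complex id, for deterministic output — else **loop** if the TSS lies in
some complex span, else **outside**. A gene with no complex can still be
**stand-alone-associated** if its TSS is within the stand-alone window
(default 20 kb) of a binding site external to every complex anchor. The
±20 kb rule is applied to the TSS point, not a promoter interval.

## Transitions and disruption

For every gene anchored in a pre-treatment (Pol II) complex, the
post-treatment (ERα) state gives one of four transitions:
anchor-to-anchor, anchor-to-loop, anchor-to-stand-alone, anchor-to-none.
The fourth category is ours: the first three do not exhaust the anchor
genes, and an exhaustive partition is needed for counts to reconcile.
Disruption is *inferred*, never observed: `disrupted := transition ≠
anchor-to-anchor`. Stand-alone sites are recomputed as post-treatment
sites not overlapping any ERα complex anchor.

Homogeneity of the induced vs repressed transition distributions is
tested with the Pearson chi-squared statistic (no continuity
correction), either on the full 2×k category table or collapsed to
2×2 disrupted/retained; a zero expected cell raises an error advising
collapse. Group comparisons use Welch's t for unpaired data (safer
default when only "t-test" is specified) and a one-sample t on
differences for paired data; zero-variance inputs resolve by convention
(equal constants → p = 1; constant nonzero paired shift → p = 0,
flagged degenerate).

## Consensus cistromes

Peaks from all studies are pooled and clustered transitively by ≥1 bp
overlap; a study supports a cluster if any of its peaks belongs to it
(site-level, not base-level, voting), and clusters with support ≥
`min_studies` (default 2) are emitted as their merged span. Merged span
rather than intersection: intersection would shrink sites asymmetrically
across studies. With `min_studies=1` the operation reduces exactly to
interval merging.

## Signal metrics

All quantities are RPM (`counts × 10⁶ / library size`); the library size
is the total read count across both strand files unless supplied.
GRO-seq signal is represented by read 5′-end positions with strand taken
from the read — the standard GRO-seq convention, and the one that makes
the ±300 bp window well defined.

Metagene profiles keep per-bp flanks around TSS and TES (500 bp for
Pol II ChIP-style profiles, 1 kb for GRO-seq) and rescale each gene body
(flank past TSS to flank before TES, minus strand flipped) with a
natural cubic spline evaluated at 1,000 equispaced points including both
endpoints, clipped at 0, then averaged into 100 bins of 10 points.
Natural boundary conditions are the common default where none is
specified; a spline through constant data is constant, so flat coverage
yields a flat metagene, and the spline is exact on linear ramps — both
properties are pinned by tests. Genes with bodies shorter than
`min_gene_length` (default 2 kb) are excluded and counted: splines on
near-empty bodies are ill-posed.

The pause ratio contrasts *densities* (RPM per kb), not raw totals —
regions of very different lengths are only comparable as densities; a
raw-total mode is kept behind a flag. The TSS window is ±300 bp; the
body runs from TSS+300 to the TES, independent of the metagene flank.
One pseudocount read is added to each region's raw count by default so
the ratio stays defined on sparse genes; with the pseudocount off a
zero-read body yields an undefined, flagged ratio.

## Permutation enrichment

The null model relocates every query interval independently and
uniformly within its own chromosome, preserving length and allowing
overlaps — the simplest length-preserving null. Statistics: base-level
Jaccard after internal merging, or the mean distance from promoters
(TSS ± 1 kb) to the nearest marker peak, where a promoter on a
chromosome without markers contributes its chromosome length as a
finite maximal-distance sentinel. Tests are one-sided with the
direction declared by the caller; p-values use the +1 correction,
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`, so p > 0 always. Default
`n_perm` is 500. Fixed seeds give bit-identical null distributions.
Multiple-testing correction across factor/marker pairs is left to the
caller.

## Synthetic study generator

The generator is truth-first: labels are sampled, signal is placed to
match them, and the truth table is then re-derived from the emitted
geometry by independent brute-force scans (plain loops, no shared code
with the pipeline's indexed implementations), so truth always agrees
with the files even when placements interact.

Defaults: 4 chromosomes × 5 Mb; 800 genes with lognormal lengths
(log-mean 9.5, log-sd 0.6, truncated to 2–200 kb), 30% induced / 25%
repressed / 45% nonresponsive; complexes with 2 + Poisson(1) anchors of
width U[1, 4] kb; each responsive gene gets its own complex (anchor over
the TSS with probability `p_tss_in_anchor` = 0.9, otherwise flanking
anchors with the TSS on loop DNA), plus 250 background complexes
containing no responsive TSS. One complex per responsive gene keeps the
class-conditional disruption probabilities well defined, since
disruption is realized per complex and inherited by its gene. Genes are
placed with a 12 kb minimum TSS separation so an anchor covering one TSS
can never sit inside another TSS's ±5 kb window; anchors are placed by
rejection sampling so that no anchor falls within the anchor window of
any TSS it was not aimed at, and anchors never overlap across complexes
(so the pipeline's union–find reconstructs exactly the emitted
complexes).

ERα sites: Poisson(3) per complex inside anchors plus background at
1 per 500 kb; three pseudo-studies apply 20% per-site dropout and
±150 bp edge jitter. Pioneer peaks (FoxA1, GATA3) co-occur with ER
sites at 70%/50% plus background. An active-promoter histone-marker
track places a peak within ±500 bp of 80% of responsive TSSs.

Disruption probabilities default to 0.86 for repressed-gene and 0.49
for induced-gene complexes; a disrupted complex becomes a loop-type ERα
complex (p 0.4), a stand-alone site within 20 kb of the TSS (p 0.4), or
nothing (p 0.2), while retained complexes re-emit their anchors as ERα
complexes.

GRO-seq-like reads: per-gene pause ratios are lognormal with log-means
ln 8 (induced), ln 2 (repressed), ln 3 (nonresponsive; chosen between
the two as a plausible unperturbed level) and log-sd 0.4; read counts
are Poisson with intensities set by the ratio and a lognormal per-gene
body rate, placed uniformly within the TSS window and body (no peak
shape), with a 20% antisense component at the TSS. Post-treatment,
induced bodies scale by k_elong = 3 (ratio drops threefold); repressed
genes scale TSS *and* body by k_rep = 0.4 with antisense halved, so
their pause ratio is unchanged while initiation falls — matching the
observation that repression acts on initiation. Each condition is
normalized to 2 × 10⁶ total reads; because RPM cannot see composition
shifts, absolute densities move slightly with the renormalization, but
the pause ratio is depth-free. The recorded truth ratio equals the
intensity ratio exactly.

What the generator does not emulate: read-level sequencing error,
mappability, peak shape, copy-number structure, multi-isoform genes,
inter-chromosomal interactions, and any dependence of disruption on
prior ERα occupancy (the ERα-in-anchor flag is generated but disruption
is sampled independently of it). Passing recovery tests therefore shows
the inference machinery is correct under the stated sampling model, not
that real libraries satisfy that model.

## Problem sizes and determinism

The analysis scripts and the end-to-end checks run the generator at its
default scale (800 genes, 2 × 10⁶ reads per condition, ~600 complexes),
with class counts 213/144/443 and `p_tss_in_anchor = 1` so the number of
induced-/repressed-gene complexes mirrors the published class sizes the
disruption fractions are conditioned on. Calibration and power checks
use reduced designs (200 replicate permutation tests at n_perm = 199;
100 paired-test replicates of 40 genes) chosen to give stable rates at
desk scale. Every random stage takes an explicit seed; simulation
output, pipeline reports and permutation null distributions are
byte-identical under a fixed seed and config.

## Known limitations

- The disruption inference is operational: a retained complex whose
  anchors move more than the anchor window away from a TSS is counted
  disrupted, and nothing distinguishes "complex gone" from "complex
  rearranged beyond recognition".
- Jaccard enrichment against broad complex spans has limited contrast
  when spans cover a large genome fraction; anchors-only references
  sharpen it.
- The uniform-relocation null ignores chromatin accessibility and gene
  density structure; a gap-preserving circular-shift null would be a
  natural alternative and is noted as future work.
- The consensus rule counts studies at cluster level; two distinct sites
  of one study falling in one cluster count once.
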