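# loopshift

Integrative analysis of how estrogen-responsive genes sit inside
higher-order chromatin complexes before and after estrogen treatment —
and what happens to those complexes when the hormone arrives.

In MCF-7 breast cancer cells, Pol II-associated ChIA-PET complexes tether
loops of DNA at *anchor regions*. A gene whose TSS falls within ±5 kb of
an anchor is an **anchor gene**; a gene inside the complex span but away
from anchors is a **loop gene**. After treatment, the same genes can be
re-examined against ERα-associated complexes: a pre-treatment anchor gene
that is no longer anchored (it became a loop gene, sits only near a
non-interacting "stand-alone" ERα site within ±20 kb, or sees nothing) is
evidence that its original complex was **disrupted**. Combined with
GRO-seq nascent transcription — the **pause ratio**
`(RPM/kb in TSS ± 300 bp) / (RPM/kb in gene body)` — this separates
regulation by transcription elongation (induced genes: highly paused
before treatment, pausing released after) from regulation by initiation
(repressed genes).

The package provides, as a reusable library under `src/loopshift/`:

- interval algebra and strict readers/writers for BED, BEDPE, bedGraph,
  refFlat-like gene tables and response tables (`core`, `io`);
- consensus cistrome construction across ChIP-seq studies and factor
  co-occurrence (`cistrome`);
- chromatin-complex assembly from interaction pairs (union–find over
  anchors) and anchor/loop/outside gene categorization (`complexes`);
- transition classification, disruption inference, chi-squared and
  t tests (`transitions`);
- RPM normalization, spline-scaled metagene profiles, initiation rates
  and pause ratios (`signal`);
- permutation tests for spatial association (Jaccard, promoter–marker
  proximity) (`enrichment`);
- a truth-first synthetic study generator emulating the joint structure
  of all inputs (`simulate`), and a config-driven end-to-end pipeline
  (`pipeline`).

The numbered scripts under `analysis/` run the study end to end on
synthetic data and narrate each step.

## Worked example

```sh
python analysis/01_simulate.py    # writes results/data/
python analysis/04_transitions.py
```

prints (seed 7, 213 induced-gene and 144 repressed-gene complexes with
disruption probabilities 0.49 and 0.86):

```
repressed: 128/144 disrupted (89%)  {'anchor-to-loop': 104, 'anchor-to-anchor': 16, 'anchor-to-stand-alone': 16, 'anchor-to-none': 8}
induced: 102/213 disrupted (48%)  {'anchor-to-anchor': 111, 'anchor-to-loop': 78, 'anchor-to-stand-alone': 20, 'anchor-to-none': 4}
chi-squared (disrupted/retained x class): stat 63.0, df 1, p 2.05e-15
```

i.e. the pipeline re-derives, purely from the emitted BEDPE/BED files,
that repressed-gene complexes are disrupted far more often than
induced-gene complexes, and the two transition distributions differ
(chi-squared on the collapsed disrupted/retained table). Running
`analysis/05_pausing.py` then recovers the simulated pausing structure
(Spearman 0.99 against truth; induced pause ratio drops from a median of
8.3 to 2.8 after the simulated elongation increase).

Equivalent single-call form:

```python
from loopshift import RunConfig, run_pipeline
report = run_pipeline(RunConfig(data_dir="results/data", out_dir="results",
                                seed=7, simulate=True))
```

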