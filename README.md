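# crosstf

Cross-species comparison of transcription-factor ChIP-seq binding.

When the same transcription factors are profiled in two species — the
motivating case is the reprogramming factors Oct4, Sox2, Klf4 and c-Myc
(OSKM) in human and mouse fibroblasts — a natural question is which binding
events are conserved, and what distinguishes conserved sites from the rest.
`crosstf` implements that comparison as a tested, reusable pipeline:

* **Synteny classes.** A chain-alignment interval mapper (liftOver-style,
  aligned-base coverage cutoff 0.5) sorts each source-species peak into
  **SC** (syntenic conserved: orthologous sequence *and* a same-factor peak
  at the mapped location), **SU** (syntenic unconserved: orthologous
  sequence, no binding in the other species) or **UN** (unsyntenic: no
  orthologous sequence).
* **Combinatorial binding.** Summits of different factors within 100 bp are
  "co-" binding events; a summit ≥ 500 bp from every other factor's summits
  is "solo". Enrichment is log2(observed/expected) against a
  `bedtools shuffle`-style uniform re-placement null.
* **Chromatin states.** A K-state hidden Markov model with independent
  Bernoulli emissions per histone mark over 200 bp bins (the ChromHMM model
  family), trained by Baum–Welch on the *concatenated* corpus of both
  genomes so one set of emission probabilities describes both species.
* **Conservation classifier.** Each syntenic peak gets a cross-species
  chromatin-state pair and a motif-occurrence pair (PWM scanning with an
  exact, DP-computed score→p-value map at p ≤ 0.001). The K×K state-pair
  and 2×2 motif-pair frequency matrices of the SC and SU classes give
  smoothed log2 ratio matrices; a peak's naive-Bayes score is

  `score(peak) = log2 R_state[s_target, s_source] + log2 R_motif[m_target, m_source]`

  and ranking peaks by that score yields a ROC AUC for motif-only,
  state-only and combined models.
* **Annotation.** TSS-distance distributions, nearest-TSS target genes with
  an exact hypergeometric cross-species target-overlap test, repeat-family
  association (full containment rule) and binding persistence into the
  pluripotent state, per conservation class.

Because the original study inputs are two full genomes of ChIP-seq data,
the package ships a **synthetic two-species dataset generator**
(`crosstf.synthgen`) that emulates the study design at desk scale with
complete ground truth: a chain covering a configurable syntenic fraction
(default 40%), per-factor planted SC fractions (4 / 4.5 / 10.9 / 34.4%),
syntenic peak fractions (74 / 80 / 73 / 89%), motif planting at 53% for
conserved vs 35% for unconserved peaks, concentrated cross-species state
transitions at conserved sites, strength–conservation correlation,
repeat-biased unsyntenic peaks, and class-dependent ESC persistence
(56 / 17 / 23%). Every downstream stage is validated by recovering what was
planted.

## Worked example

```python
from crosstf.synthgen import SynthConfig, generate
from crosstf import synteny

ds = generate(SynthConfig(seed=1))          # two genomes, chain, peaks, ...
index = synteny.ChainIndex(ds.scaffold.chains)
for factor in ds.cfg.factors:
    calls = synteny.classify_peaks(
        ds.peaks.source[factor], ds.peaks.target[factor], index
    )
    sc = sum(c.klass == "SC" for c in calls)
    print(factor, f"syntenic={synteny.syntenic_rate(calls):.3f}",
          f"SC={sc / len(calls):.3f}")
```

prints

```
Oct4 syntenic=0.740 SC=0.040
Sox2 syntenic=0.800 SC=0.045
Klf4 syntenic=0.730 SC=0.109
cMyc syntenic=0.890 SC=0.344
```

i.e. the classifier recovers the generator's planted per-factor syntenic
and conserved fractions exactly (the generator places peaks fully inside or
fully outside chain blocks, so with zero coordinate noise the classes are
unambiguous).

The same dataset drives the full pipeline from the shell:

```bash
crosstf run --out out/            # all stages on the default synthetic config
crosstf synth --seed 5 --out ds/  # just emit a dataset as FASTA/chain/narrowPeak/...
crosstf classify --peaks-from ds/peaks/Oct4_mouse.narrowPeak \
    --peaks-to ds/peaks/Oct4_human.narrowPeak \
    --chain ds/source_to_target.chain --out calls.tsv
```

`crosstf run` writes one TSV/JSON per stage plus tidy per-figure-panel
tables under `out/figures/`, and reruns are byte-identical for a fixed
config.

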