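# Methods

This note documents the models, the synthetic study design, numerical
choices and known limitations of `crosstf`. Empirical statements here are
limited to what the test suite and `scripts/acceptance.py` themselves
compute.

## Chain mapping and conservation classes

Intervals are mapped between genomes through a UCSC chain alignment with
the source species on the chain *target* (t) side (`over.chain`
convention). For an interval the mapper considers every chain on that
chromosome, computes the number of interval bases inside aligned blocks,
keeps the single best-covering chain (ties broken by chain score —
split mappings across chains are rejected, matching liftOver's default),
and succeeds when coverage ≥ `min_match`. The mapped interval is the
`[min, max+1)` span of the per-base images; for a `-`-strand query the
file's reversed coordinates are flipped with `q_size − pos − 1`. A
brute-force per-base image map is the test oracle (50 random chains ×
1 000 random intervals, exact agreement on span and on success at the 0.5
cutoff).

`min_match` is interpreted as **aligned-base coverage** of the source
interval (`liftOver -minMatch` semantics). The alternative reading —
sequence identity inside blocks — is not re-checked; chain files assert
alignment, and coverage is the criterion the cutoff value 0.5 historically
belongs to.

Classes: **UN** if mapping fails (`no_chain` or `below_min_match`);
otherwise **SC** if the mapped interval overlaps (≥ 1 bp) a same-factor
peak in the other species, with the maximal-overlap peak as partner
(tie → leftmost); otherwise **SU**. The ≥ 1 bp overlap criterion is a
design choice (the alternative, partner summit inside the mapped interval,
is available via `MapperConfig.partner_criterion`). Partner peaks are
same-factor; the per-factor conservation fractions are only meaningful
that way.

The background conservation simulation re-places *both* peak sets
uniformly at random — per peak, lengths preserved, chromosome assignment
preserved, overlaps allowed (the `bedtools shuffle` defaults) — and
records the SC rate per iteration (default 1 000 iterations; the pipeline
uses 200 at desk scale).

## Combinatorial and solo binding

Summits are single-linkage clustered per chromosome; "within 100 bp" is
inclusive (≤ 100) and "at least 500 bp" is inclusive (≥ 500), so peaks
101–499 bp from another factor's summit are neither co nor solo.
Same-factor peaks inside one cluster count once toward that factor's
presence. The null re-places each factor's peaks uniformly
(length/chromosome preserving) and re-runs clustering and solo calls;
log2 ratios use a 0.5 pseudocount (Haldane–Anscombe). The two-factor
collision probability has a closed form used as an analytic oracle.

## Chromatin-state model

The model is a K-state HMM with independent Bernoulli emissions per
histone mark over fixed 200 bp bins — the ChromHMM model family,
re-implemented in numpy (nothing external is called; no available HMM
library implements multivariate-Bernoulli emissions). Counts are binarized
per mark against a global Poisson rate equal to the mean bin count, "on"
when the upper tail P[X ≥ count] ≤ 1e-4 (ChromHMM's default convention).
Both species' binarized chromosomes are pooled into one training corpus —
the "concatenated genome" — so a single emission table describes both;
every chromosome is an independent chain and no transition crosses a
segment boundary.

Training is Baum–Welch EM with scaled forward–backward. Initialization
seeds the emission rows from the K most frequent *distinct* binary mark
patterns in the data, after a greedy diversity pass that skips a candidate
within Hamming distance 1 of an already chosen (more frequent) pattern —
one-bit neighbours of a common pattern are almost always its noise shadow,
and seeding two states on them makes EM merge genuinely distinct states.
Rows are shrunk toward ½ (0.7·pattern + 0.15) plus a small seeded jitter.
Transitions start uniform with 0.9 self-transition mass. The
log-likelihood is asserted non-decreasing at every iteration; training
stops at relative improvement ≤ 1e-4 or `max_iter`. A state that loses all
responsibility triggers one re-seed, then an error. K = 1 is handled in
closed form (emissions = empirical mark frequencies). Forward likelihood
is tested against exhaustive path enumeration (≤ 10 bins, K ≤ 3).

Decoding is per-bin posterior argmax (ChromHMM's behaviour; Viterbi is
available). Peak state assignment takes the state of maximal bp overlap
with the peak, ties to the summit-bin state, then to the lower id. State
enrichment is log2((peak fraction + ε)/(genome fraction + ε)), ε = 1e-6.
State ids are arbitrary; human-readable labels are user-supplied, never
inferred. A separate larger model (e.g. 18 states over 9 marks) is just a
different (K, mark list) parameterization, not a second code path.

## Motif scanning

PFM columns are normalized and converted to log2 likelihood ratios against
the background (uniform by default) with pseudocount
`log2((p + α·bg)/((1+α)·bg))`, α = 0.01; with α = 0, −∞ cells clamp at a
floor. Scores are discretized to a 0.01 lattice and the exact background
distribution of the window score is computed by positional convolution
(the standard DP used by FIMO/MOODS-style exact p-values); enumeration
over all 4^w words is the oracle for w ≤ 6. Both strands are scanned,
windows containing N are skipped, a window is a hit when its exact
upper-tail probability is ≤ 0.001, and a peak "has the motif" when any
window inside it hits — per-window p-values with no multiple-testing
correction, matching the per-peak presence/absence usage. Consequently
~200 bp motif-free peaks still flag at a ~10–15% background rate for a
width-10 high-information motif; class *differences* in motif fraction
ride on top of that common floor. For the orthologous side of a syntenic
peak the full mapped interval is scanned. De novo discovery is out of
scope; a utility exports summit-centred sequences of the strongest peaks
for external tools.

## Conservation classifier

For one factor's syntenic peaks, the K×K state-pair matrix (rows =
target-species state, columns = source-species state; a transpose flag
exists) and the 2×2 motif-pair matrix are tabulated separately for SC and
SU as fractions. The classifier stores their smoothed log2 ratios with
Laplace pseudocount α = 1 on counts (unsmoothed empty cells are infinite);
a peak's score is the state cell, the motif cell, or their sum. AUC is the
rank-based Mann–Whitney statistic with half-credit ties, cross-checked
against brute-force pairwise counting and scikit-learn. Evaluation offers
resubstitution (train = score set; the simplest reading of a fit on all
syntenic peaks, optimistically biased) and stratified k-fold (pooled
held-out scores). Under a no-signal null the k-fold estimate carries a
small negative bias (≈ −0.01 at n = 2 000, K = 15): removing a test peak
from training shifts its own cell's log-odds away from its class — the
usual leave-out anti-bias of discrete naive Bayes. Feature extraction for
SU peaks uses the chromatin state and motif flag of the *mapped*
orthologous interval (no partner peak exists there), the only coherent
cross-species reading.

## Synthetic study design

The generator is a pure function of `SynthConfig` (seed included); each
stage draws from its own PRNG stream keyed by `(seed, stage name)`, so
adding a stage never perturbs earlier outputs. Defaults are the study
conditions:

| parameter | default | meaning |
| --- | --- | --- |
| genomes | 2 × 10 Mb per species | two chromosomes each, random sequence |
| `syntenic_fraction` | 0.40 | aligned chain-block coverage of the source genome (the genome-wide background rate) |
| `n_blocks` | 40 | syntenic segments; 1–3 aligned sub-blocks with small dt/dq gaps |
| factors / peaks | OSKM × 1 000 | 200 bp peaks on a bin-aligned site lattice |
| `syntenic_peak_fraction` | .74/.80/.73/.89 | per-factor planted SC+SU fraction |
| `sc_fraction` | .04/.045/.109/.344 | per-factor planted SC fraction (deterministic rounding) |
| `cobind_fraction` | 0.30 | fraction of each factor's peaks at shared sites (subset sizes 2–4, weights .4/.3/.3); all other sites ≥ 600 bp apart so they are unambiguous "solo" |
| `strength_conservation_effect` | +15 | additive shift of SC −log10(q); base strength Gamma(2, 10) |
| `motif_rate_sc` / `motif_rate_unc` | 0.53 / 0.35 | probability of a planted consensus instance at the summit; SC instances are written identically at both orthologous positions |
| marks / states | 5 marks, 15 states | emission table: distinct even-parity mark patterns (pairwise Hamming ≥ 2, hence L1 ≥ 0.5) at 0.95/0.02 |
| `lambda_high` / `lambda_low` | 40 / 0.05 | Poisson count rates where a mark is/isn't emitted; chosen so signal bins clear the 1e-4 Poisson binarization threshold with ~0.99 sensitivity, like strongly enriched ChIP signal |
| `quiescent_weight` | 25 | stationary weight of the empty-pattern state (~64% of bins), with 0.9 self-transition |
| `state_concentration` | 0.8 | probability an SC peak draws the *same* active state in both species; SU peaks always draw independently |
| `esc_persistence` | .56/.17/.23 | per-class probability a 48 h peak persists into the pluripotent set |
| `repeat_assoc_rate` | .05/.10/.25 | per-class probability of a repeat planted fully inside the peak (UN highest), over a 50/Mb uniform background |
| `n_genes` | 2 000 | TSS pairs; genes inside blocks get their ortholog at the mapped position |

Half of each factor's target-species background peaks reuse syntenic sites
bound by *other* factors in the source species (shared open chromatin).
This plants the cross-species co-targeting signal the overlap test
measures; placing them only at unused sites provably anti-correlates the
two species' target-gene sets.

Peaks are planted fully inside or fully outside chain blocks, so with zero
coordinate noise the truth labels are unambiguous and classification
recovery is exact; a `straddle_fraction` knob instead centres SU peaks on
block starts, giving mapped coverage of exactly 0.5 to exercise the cutoff
boundary.

What the generator does **not** emulate: read-level noise and peak-calling
uncertainty, nucleotide-level evolutionary divergence inside aligned
blocks (block sequence is copied verbatim; only motif planting
distinguishes the copies), inversions (synthetic chains are `+`-strand;
the mapper's `-`-strand path is covered by hand-built chains in tests),
realistic repeat structure, and distance-dependent co-binding decay.
Passing tests therefore demonstrate correctness of the analysis machinery
on a faithful miniature of the study design, not robustness to the noise
sources of real ChIP-seq.

## Problem sizes and determinism

Desk-scale defaults: 20 Mb per species (100 000 bins each), 4 000 source
peaks, 200 background-conservation shuffles, 100 co-binding shuffles, 50
spectrum shuffles, HMM `max_iter` 30. The full pipeline is a few minutes
on one core and is byte-identical under a fixed config (the report
excludes the output path and contains no timestamps). The exact
hypergeometric tail is computed in log space (gammaln + logsumexp), agrees
with integer enumeration to < 1e-12 relative error for N ≤ 60, and at the
published scale (N = 15 789) yields p ≈ 3e-16 — reported as the exact
value rather than a "< 1e-16" bound.

## Known limitations

* Resubstitution AUC is optimistically biased; k-fold is reported
  alongside it, and carries the small discrete-NB leave-out anti-bias
  described above.
* The exact PWM p-value lattice bounds discretization error by
  width × step; p-values are per-window, and per-peak flags inherit a
  length-dependent false-positive floor.
* The mapper rejects split mappings across chains rather than stitching
  them; reciprocal-best filtering is out of scope.
* `assign_peak_state` errors on unsegmented chromosomes rather than
  guessing; pipelines must segment every chromosome peaks live on.
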