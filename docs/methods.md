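# Methods

## Model

Knockout screens report, per sgRNA, the log2 fold change of its abundance in
the selected population versus the plasmid library. Cutting inside highly
amplified DNA depletes cells independently of gene function, and the effect
tracks *focal* amplification rather than absolute copy number: a gene at 4
copies on a tetraploid genome behaves like a diploid gene, while a tandem
duplication stack on an otherwise diploid chromosome is strongly depleting.

The correction therefore regresses fold change on the **copy-number ratio**
— segment copies divided by chromosome copies — rather than on copy number.
Both quantities are size-weighted means over the copy-number segmentation;
chromosome copy number is kept continuous (integer rounding is applied only
when forming strata labels for the benchmarks, because the observed ratios of
interest, e.g. 1.58 or 4.05, are non-integer quotients).

Per sample, every segment with at least `min_guides = 10` assigned sgRNAs
contributes one training point: its copy-number ratio (x) and the mean fold
change of its guides (y). The regression is a Gaussian process with prior
mean zero and kernel

    K(x, x') = σ² · exp(−(x − x')² / (2 θ²)) + ψ · 1[x = x']

a constant-scaled squared exponential plus white noise. Hyperparameters are
fitted by maximising the log marginal likelihood, with three random restarts
drawn log-uniformly within bounds from a seeded generator, via
scikit-learn's `GaussianProcessRegressor`. Bounds: θ ∈ [1e−5, 10] (ratio
units — essentially unconstrained smoothness over the observed ratio range),
σ² and ψ ∈ [1e−3, 10] (log2-fold-change variance units; the paper-level
definition fixes only θ's bounds, so σ²/ψ bounds are configuration with wide
defaults). The predicted bias at a ratio is the posterior mean of the latent
(noise-free) function; the predictive standard deviation is reported for the
QC plot. Corrected guide fold change = original − predicted bias, exactly;
gene-level corrected values are re-aggregated as unweighted means of the
gene's surviving guides. Guides in segments below `min_guides` still receive
predictions — the filter affects training only. Guides whose midpoint falls
outside every segment pass through uncorrected and flagged.

Fitting is strictly per sample: the model for one sample never sees another
sample's data, which lets sample-specific context (ploidy, global screen
efficacy) be absorbed by the fitted mean instead of being borrowed across
a panel. One consequence worth stating: because the GP cannot distinguish
injected copy-number bias from real depletion that happens to be uniform
across segments (essential genes at every ratio), the fitted curve includes
the average true-depletion level; corrected values are therefore centred on
the screen's average rather than on absolute zero.

## Fold-change processing

Guides with raw plasmid count below 30 are discarded before anything else
(strictly below — 30 is kept). Each sample is then scaled to the mean raw
library size; the normalisation constant is arbitrary for fold changes
(it cancels against the plasmid column up to the pseudocount) but preserving
count magnitude keeps the filter interpretable. Fold change is
log2(norm + 1) − log2(norm_plasmid + 1); the pseudocount of 1 (configurable)
guards log(0) with minimal distortion above the 30-count floor. Gene-level
values are unweighted means of guide values; replicates are fold-changed
separately and averaged afterwards. Optional rescaling sets the mean fold
change of a supplied known-essential set to exactly −1; it is applied after
correction when requested, is idempotent and linear, and refuses screens
whose essential mean is non-negative (a QC failure).

Because the normalisation target is the mean of all column totals, removing
a sample from the count matrix rescales the remaining columns by a common
factor. This cancels exactly in the fold change except through the
pseudocount, leaving end-to-end differences of order 1e−4 log2 units; the
correction stage itself is exactly invariant given a sample's fold-change
vector. The tests assert the exact invariance at the correction stage.

## Benchmarks

Gene-independent bias is quantified by recall of *non-expressed* genes
(RPKM < 1, strict) among ranked fold changes: genes are sorted ascending
(most depleted first, ties broken by stable lexicographic gene order), and
the AURC of a gene set is the mean of recall(k) over all N ranks — the
Riemann sum of the right-continuous recall step curve, fixed exactly by a
brute-force oracle in the tests. 0.5 is no enrichment. Strata are defined by
floor-integer copy number ({0..9, 10+}), ratio bins ({<1, [1,2), [2,3),
[3,4), ≥4}, configurable), sample ploidy, or rounded chromosome copies;
strata with fewer than 5 genes are skipped. Essential-gene AURC before
versus after correction measures whether real signal was preserved.

## SV overlap

Tandem-duplication and deletion calls enter only if an assembly score is
present (the caller's assembled-evidence criterion); matching to segments
requires both breakpoints within 10 kb (inclusive) of the segment start and
end on the same chromosome, and all qualifying pairs are reported — both the
pair count and the unique-SV count are returned since one event may match
several adjacent segmentations. Class comparison reports per-class n and
medians plus Welch's unequal-variance t test (two-sided); two zero-variance
classes are flagged `degenerate` (t = 0, p = 1 when the means agree; p = 0
otherwise) instead of propagating a silent NaN.

## Synthetic screens

The generator builds what the method needs to be tested against, with known
ground truth:

* 8 chromosomes of 10 Mb; two cleanly diploid, two wholly duplicated
  (copy number 4, ratio exactly 1 — the negative control that distinguishes
  ratio-based from absolute-CN-based correction), four carrying focal
  events: six 20 kb focal segments each (one deletion at 0.5× base ploidy,
  five amplifications whose multipliers jointly cover ~1.3–4.6×). Focal
  segments are short relative to the chromosome so the size-weighted
  chromosome copy number stays near base ploidy and segment ratios land near
  their multipliers.
* 200 genes per background segment and 9 per focal segment, 4 guides per
  gene (~11.4k genes, ~46k guides, 80 segments, all guide-eligible). The
  proportions matter: focal passengers are ~2% of genes (so correction
  cannot materially reshuffle essential-gene recall, as at cohort scale) and
  focal segments carry enough genes that their expected essential-gene load
  matches the genome-wide rate — with very few genes per focal segment the
  background and focal training points would be asymmetrically contaminated
  by essential depletion.
* Injected bias b(r) = −β · min(max(r − 1, 0), 3), β = 1: piecewise linear
  in ratio, zero at and below 1, saturating at ratio 4 — monotone enrichment
  up to a "≥4" plateau.
* Essentials (5% of genes, true fold change −1) and non-expressed flags
  (40% of non-essential genes, RPKM drawn below 1; others ≥ 2) assigned
  uniformly at random. Essentials are always expressed.
* Counts: per-guide plasmid abundance log-normal around depth 500 (1% of
  guides deliberately near-zero to exercise the 30-count filter); sample
  expectation = abundance · 2^(true fc + bias + N(0, 0.3)) per replicate
  (two replicates); Poisson draws. Poisson was chosen over negative binomial
  for analytic tractability of the expectations the tests assert.
* Every focal event emits a matching tandem-duplication or deletion SV call
  with breakpoints jittered ±4 kb (inside the 10 kb matching tolerance),
  plus unscored / wrong-type decoys that the confidence filter must remove.

What the generator does **not** emulate: real genome coordinates and gene
density, guide-efficacy variation, off-target cutting, GC or position
effects within amplicons, subclonal copy number, and overdispersed counts.
Passing tests therefore demonstrate that the estimator recovers the model it
assumes under realistic noise magnitudes — not that real screens satisfy
those assumptions.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere; guide↦segment assignment is
  by midpoint (floor of (start+end)/2) containment, so a guide is never
  split across segments and boundary midpoints go to the right-hand segment.
* Chromosome names are matched verbatim; no "chr" normalisation.
* The fit requires ≥ 3 eligible segments spanning ≥ 2 distinct ratios;
  otherwise the sample is refused with a clear error. A sample whose ratios
  are all ≈ 1 fits a constant-plus-noise model and the correction subtracts
  roughly the global mean — accepted and logged.
* With prior mean 0 and bounded σ², a constant target is recovered only up
  to shrinkage ~ψ/(n·σ̄²); with the default ψ lower bound (1e−3) this is
  ~7e−3, and reaches <1e−6 only when the ψ lower bound is made tiny. The
  tests assert the tight recovery under a tiny ψ bound and document the
  default-bound behaviour.
* Refitting with the same seed is bit-reproducible; restart draws come from
  the seeded optimizer state.
* Missing values in output TSVs are empty strings; numeric output uses
  8 significant digits (round-trips to ≥ 6).

## Problem sizes

The default synthetic screen (~46k guides, 80 training segments) runs the
full pipeline in ~2 s; GP training cost is cubic only in the number of
segments, which is small by construction in real segmentations too. Tests
use a 4-chromosome miniature where the full default is not needed.
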