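# crispy-screen

Per-sample correction of copy-number-driven loss-of-fitness bias in
CRISPR-Cas9 knockout screens.

## The problem

In a pooled knockout screen, Cas9 cutting at a locus present in many DNA
copies depletes the cell regardless of the targeted gene's function. The
strength of this gene-independent loss-of-fitness (LOF) effect depends on
*how* the amplification arose: focal events such as tandem duplications bias
fold changes strongly, while amplifications that simply track whole-chromosome
or whole-genome duplication have little or no effect. Correcting on absolute
copy number therefore over-corrects high-ploidy samples.

The copy-number **ratio** separates the two regimes. For a gene (or segment)
*g* on chromosome *c*,

```
ratio(g) = CN(g) / CN(c)
```

where both copy numbers are size-weighted means over the copy-number
segmentation: `CN(interval) = Σ_s cn_s · overlap(s) / Σ_s overlap(s)`.
A ratio ≈ 1 means the gene moved with its chromosome (no expected bias), a
ratio > 1 flags a focal amplification, < 1 a focal deletion. Sample ploidy is
the genome-wide size-weighted mean copy number.

## The correction

For each sample independently:

1. sgRNA counts are filtered (raw plasmid count < 30 discarded), library-size
   normalised, and turned into log2 fold changes versus the plasmid control.
2. Guides are assigned to copy-number segments (midpoint containment); each
   segment with ≥ 10 guides contributes a training point
   (ratio, mean guide fold change).
3. A Gaussian-process regression with kernel

   ```
   K(x, x') = σ² · exp(−(x − x')² / (2θ²)) + ψ·1[x = x']
   ```

   (θ ∈ [1e−5, 10], maximum-marginal-likelihood fit with 3 seeded random
   restarts) models segment mean fold change as a function of segment ratio.
4. The GP posterior mean at each guide's segment ratio is the predicted bias
   and is subtracted from the guide's fold change; gene-level values are
   re-aggregated from corrected guides.

Because the fit is per sample, cell-specific context — ploidy, global screen
efficacy — is absorbed automatically and nothing leaks across samples.

The package also provides the benchmarking used to establish the effect
(recall curves / AURC of non-expressed genes stratified by copy number,
ratio, ploidy or chromosome copies), SV-to-segment breakpoint matching
(confident tandem duplications / deletions, 10 kb tolerance, Welch's t
comparison between classes), and a seeded synthetic-screen generator with
known ground truth.

## Worked example

`python examples/simulate_and_correct.py` simulates a screen (8 chromosomes,
80 segments, ~11k genes, whole-chromosome duplications plus focal
amplifications carrying an injected bias) and corrects it:

```
simulated 45664 guides over 11416 genes, 80 segments
fitted kernel: sigma^2 = 2.693, theta = 0.774, psi = 0.0015 (log marginal likelihood 114.0)
bias-curve RMSE vs injected function: 0.067 (training ratios 0.49..4.51)
non-expressed genes at ratio >= 2 (n=51): mean fc -2.17 before, +0.03 after correction
```

The fitted GP recovers the injected bias curve to 0.067 log2 units, and
non-expressed genes on focally amplified segments — which by construction
have no real fitness effect — move from a spurious mean fold change of −2.17
to ≈ 0. `examples/benchmark_bias.py` shows the same result as stratified
AURCs (amplified strata collapse from ≈ 1.0 to ≈ 0.5 while essential-gene
recall stays ≈ 0.97), `examples/ratio_worked_example.py` walks through the
ratio arithmetic on three cell-line scenarios, and `examples/sv_matching.py`
links tandem duplications and deletions to ratio > 1 and < 1 segments.

## Command line

```
crispy simulate --out simdata --seed 1
crispy correct  --counts simdata/counts.tsv --library simdata/library.tsv \
                --segments simdata/segments.tsv --plasmid plasmid --out corrected
crispy qc       --counts ... --expression ... --corrected corrected --out qc
crispy ratio    --segments ... --annotation ... --out ratios.tsv
crispy svmatch  --sv svs.bedpe.tsv --segments ... --out svout
```

Every run writes a `run_manifest.json` with the config, seed and fitted
hyperparameters.

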