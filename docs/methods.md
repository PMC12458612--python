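# Methods

## The model

`hinnlab` implements a hierarchical input neural network for predicting
continuous cognitive scores (MMSE, MoCA, ADAS11, RAVLT-immediate style
scales) from three molecular layers — SNP dosages, DNA-methylation beta
values, and expression probes — plus demographic covariates.  The central
idea is that the network's wiring is not learned but *prescribed* by prior
regulatory biology: a binary mask `M_l` gates each inter-layer weight matrix
so that only pairs with a documented spatial or functional relationship
(cis meQTL window, promoter membership, GO annotation) can carry signal.

Each masked layer computes

    f(X, M) = act(X @ (M ⊙ W) + b)

with ⊙ the Hadamard product, so weights at masked-out positions have exactly
zero influence on the output and receive exactly zero gradient.  Omics
inputs beyond the first pass through a diagonal (one weight per feature)
scaler before being combined with the upstream stage.  The combination
operators encode the assumed direction of regulation:

* SNP → CpG-space: `Y1 = f(X_snp, M1)` (mask from ±1 Mb window links);
* methylation stage: `Y2 = act(diag(X_cpg) ⊙ Y1 + b2)` — multiplicative,
  genotype amplifies/attenuates the methylation signal;
* expression stage: `Y3 = act(diag(X_expr) / max(f(Y2, M2), ε) + b3)` —
  division, encoding methylation's inhibitory effect on transcription
  (mask from TSS200/TSS1500 promoter membership);
* GO stage: `Y4 = f(Y3, M3)` (mask from enrichment-derived annotations).

Because sparse masks can discard information, a small fully connected
"bypass" (20 units per stage by default) runs alongside the hierarchy:
`B1 = dense(X_snp)`, `B2 = dense([B1, Y2])`, `B3 = dense([B2, Y3])`.  The
head takes `[Y4, B3]` through four (batch-norm → 128-unit ReLU dense →
dropout 0.7) blocks, a 20-unit bottleneck, concatenation of the demographic
vector, one more block, and a single linear output.  Batch-norm uses
momentum 0.9 and epsilon 0.005; dense layers carry L2 regularization
(1e-4) and variance-scaling initialization.

The whole network is implemented as a small reverse-mode graph over numpy
arrays (float64).  The same recorded graph drives exact backpropagation
during training and DeepLIFT multiplier propagation during attribution.

### Architecture variants

`fully_connected` replaces all masks by ones; `randomized` redraws each
mask's 1-entries uniformly at random with the edge count preserved (a
row-degree-preserving shuffle is available as a switch); `hierarchy_only`
keeps the layer ordering but replaces elementwise coupling by
dense-then-concatenate; `drop_snp` / `drop_cpg` / `drop_expr` remove one
modality and rewire the neighbours (under `drop_cpg` the SNP stage feeds the
division denominator directly; under `drop_expr` the composed mask
`(M2 @ M3) > 0` bridges CpGs to GO terms); `no_go` connects the expression
stage straight to the head; `pgnn` is the pathway-guided baseline — all
omics concatenated into one input sparsely wired to a GO-term-width layer by
the composed feature→term annotation, identical head thereafter.  All
variants keep shapes and layer orderings fixed so comparisons isolate
connectivity.

## Feature selection

The mask structure comes from a selection pipeline run on the cohort:

1. **Genotype QC** — samples then SNPs filtered by missing rate (>5%
   removed), minor allele frequency (<5% removed, computed on non-missing
   calls), and a two-sided Hardy-Weinberg exact test (p < 1e-6 removed).
   The exact test sums conditional probabilities of heterozygote counts no
   more probable than the observed one, given the allele counts.  A config
   switch (`qc.literal_directions`) inverts both missingness and HWE
   directions for protocol-matching studies.
2. **GWAS scan** — per SNP, simple linear regression of each cognitive
   score on additive dosage over non-missing samples; two-sided t-test;
   Bonferroni adjustment over tested SNPs (BH available).  SNPs significant
   (adjusted p ≤ 0.01) in *every* phenotype are retained.
3. **Window linking** — CpGs within ±1 Mb (inclusive) of a retained SNP on
   the same chromosome become SNP→CpG edges.
4. **Promoter mapping** — strand-aware upstream distance d = TSS − pos
   ('+') or pos − TSS ('−'); d ∈ [1, 200] tags TSS200, d ∈ (200, 1500]
   TSS1500.  A linked CpG in a promoter yields CpG→probe edges for that
   gene's probes.
5. **GO enrichment** — one-sided hypergeometric over-representation of the
   promoter-selected genes against the probe-mapped universe, BH-adjusted
   (α = 0.05); passing terms contribute probe→term edges.
6. **Pruning** — iterate to a fixed point: SNPs need an outgoing edge, CpGs
   an incoming and an outgoing edge, probes an incoming edge (GO
   connectivity optional, off by default since the bypass carries
   unannotated probes).  The result is the RelationMap from which masks are
   built with deterministic chromosome/position/id orderings.

Coordinates are 0-based half-open throughout (BED convention); genotype
missingness uses a dedicated −1 sentinel so QC counts are exact.

## Training protocol

70% train / 30% test, with 20% of the training split held out for early
stopping (patience 50 epochs on validation MSE, best state restored).  The
protocol is repeated three times — each repeat re-randomizes the split and
the initialization — and metrics are reported as mean ± sd of test MAE and
MSE.  Optimizer: Adam, lr 3e-3, batch 64, squared-error loss with L2 on
dense weights, global gradient-norm clip 5.  Targets are standardized on
the training split and predictions returned on the raw scale.

Numerical choices that the bare architecture leaves open, and how this
package resolves them:

* **Division stability.** ReLU denominators can be exactly 0; the
  denominator is clamped at ε = 1e-6 (configurable) and clamp events are
  counted as telemetry.  Even so, a held-out sample can land near the clamp
  and produce an enormous ratio.  Predictions are therefore clipped to the
  training target range — cognitive scales are bounded by definition — which
  bounds the influence of such outliers without touching the forward model.
* **Masked-layer initialization.** Weights are drawn half-normal
  (nonnegative) with variance scaled by each unit's masked fan-in, and the
  denominator-layer bias starts at 1.  The structured path then begins as a
  live, near-neutral pass-through (divide by ≈1, multiply by positive
  weights) instead of a dead or exploding stage, which matters at small
  layer widths.
* **Dropout × batch-norm.** With dropout 0.7 feeding downstream batch-norm,
  inference statistics learned during training are inflated relative to
  dropout-free activations, which collapses eval-mode predictions toward
  the mean.  After each epoch the running statistics are recalibrated with
  one dropout-free pass over the training set.
* **Omics activation** is ReLU by default (tanh/sigmoid configurable);
  the loss is MSE; demographics are standardized (age, education,
  log-p-Tau) or kept as small integer codes (sex, APOE4 copies).

Classical baselines (Lasso, SVR, random forest, MLP) run on the flattened
feature matrix with the identical splits, each tuned by 10-fold CV over a
small grid on the training data.

## Attribution and cascade export

DeepLIFT with the Rescale rule, applied to the eval-mode network (frozen
normalization, no dropout): linear operations propagate multipliers through
the linear map, elementwise nonlinearities use Δoutput/Δinput (gradient
fallback when |Δinput| < 1e-7), two-input products use the symmetric
half-split rule `m_a = b_ref + Δb/2`, and the ε-clamped reciprocal is
treated as one elementwise unit.  Sum-to-delta — Σ contributions =
f(x) − f(reference) per sample — holds to float precision by construction.
The reference is the training-set feature mean (all-zeros by flag); the
per-feature score is the mean absolute per-sample contribution (signed
means also emitted), averaged across models trained on different cognitive
tests, then percentile-ranked within each molecular layer.

The Sankey export keeps the top-k features per layer by attribution and
draws a link only where both endpoints are selected *and* the RelationMap
contains the edge; GO terms are ranked by the mean attribution of their
selected upstream probes.

## Correlation analyses

Spearman rho uses midranks over pairwise-complete observations; p-values
come from the two-sided t approximation, or the fully enumerated
permutation distribution when n ≤ 9.  Methylation–expression correlations
are computed per promoter pair within CN and CI strata (CI = MCI ∪ AD),
with BH-adjusted p reported alongside raw p; significance is flagged on raw
p ≤ 0.05 by default (config switch) to match the reporting convention of
stratified promoter tables.  The same operation serves p-Tau181 against
prioritized features (per stratum) and against the cognitive scores (whole
cohort).

## The synthetic cohort generator

Because the motivating datasets are restricted-access, every stage is
exercised on simulated cohorts with a planted causal cascade.  Defaults —
500 samples; 200 SNPs, 300 CpGs, 100 genes/probes, 30 GO terms on one 50-Mb
chromosome; 5 cascades — are the package's standard study conditions.

Generative structure, in order: genotypes `Binomial(2, maf)` with maf ~
U(0.05, 0.5) (causal SNPs U(0.15, 0.5), i.e. common variants), 2% missing
calls; methylation simulated on the logit scale (baseline per CpG, causal
CpGs kept in the variable mid-range U(−1, 1)) with a per-allele meQTL slope
of 1.5 and N(0, 0.5) noise, squashed to (0,1); expression = per-gene
baseline − 2.0 × beta + N(0, 0.3) for causal genes; a standardized latent
trait takes 60% of its variance from the causal genes' expression, 10% from
covariates (age, education, APOE4), the rest noise.  Observed scores are
bounded monotone transforms of the latent trait with N(0, 0.3) test noise —
MMSE/MoCA-like increasing on 0–30, ADAS11-like decreasing on 0–70,
RAVLT-like on 0–75.  The p-Tau proxy is lognormal (median ≈ 20 pg/mL) with
correlation −0.35 to the latent trait; diagnosis is the latent tertile (top
third CN).  Causal geometry is enforced: each causal SNP lies within the
±1 Mb window of its causal CpG, which lies in its gene's TSS200/TSS1500
promoter; ~40% of null CpGs also sit in random promoters.  Each designated
enriched GO term contains the full causal gene set plus one bystander;
other terms are random 8–15 gene draws.

Effect sizes were chosen once so that the planted cascade is recoverable at
these sizes — strong cis-meQTLs and promoter effects, as the selection
thresholds (Bonferroni-adjusted p ≤ 0.01 in all four tests) otherwise
retain nothing at n = 500.  What the simulation deliberately omits: LD
structure, population stratification, batch effects, hidden confounders,
realistic beta-value bimodality, probe cross-hybridization.  Passing the
recovery tests therefore demonstrates the pipeline's internal correctness
and its ability to exploit true structure, not performance on real cohorts.

## Problem sizes in tests and the acceptance script

The bundled runs use the default cohort (n = 500) with 3 training repeats;
the end-to-end CLI demo config trims training to 150 epochs.  At these
sizes the post-selection layers are narrow (≈4 SNPs / 30 CpGs / 15 probes /
5 terms), so the 20-unit dense bypass can carry most of the predictive
information in *any* variant; the advantage of biological over randomized
wiring is real in expectation (mean test MSE orders biological ≤ randomized
across seeds) but noisy per repeat.  The seeded suite fixes the cohort and
protocol seeds for the per-repeat comparison.

## Known limitations

* The division stage is intrinsically ill-conditioned near zero
  denominators; the ε-clamp and range clipping manage, not remove, this.
* Randomized-mask ablation preserves total edge count only; in-degree
  distributions change.
* GWAS runs without covariate adjustment by default (residualization is
  available but off), and no LD-aware pruning is performed.
* Baseline hyperparameter grids are small and documented, not exhaustive.
* Checkpoint archives store raw parameter arrays; architectures must match
  exactly on load.
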