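# hinnlab

Hierarchical, biologically mask-constrained neural networks for predicting
continuous cognitive scores from multi-omics data, together with the
cross-layer feature-selection pipeline that wires them, ablation variants,
DeepLIFT-based interpretation, and stratified correlation analyses.

## Who this is for

Researchers modelling cognitive decline (or any continuous phenotype) from
SNP genotypes, DNA-methylation beta values and expression probes who want
the network architecture itself to respect known regulatory structure —
SNPs acting on nearby CpGs, promoter methylation suppressing transcription,
genes grouping into biological processes — and who need the resulting
models to be interpretable at the level of individual multi-omic cascades.

## The model

A binary mask `M_l` gates each inter-layer weight matrix, so only
biologically documented pairs can carry signal:

    f(X, M) = σ(X · (M ⊙ W) + b)

The hierarchy runs genotype → methylation → expression → GO terms:

    Y1 = f(X_snp, M1)                           # ±1 Mb meQTL-window mask
    Y2 = σ(g(X_cpg) ⊙ Y1 + b2)                  # multiplicative coupling
    Y3 = σ(g(X_expr) / max(f(Y2, M2), ε) + b3)  # inhibitory (division)
    Y4 = f(Y3, M3)                              # promoter/GO masks

where `g` is a per-feature diagonal scaler.  A 20-unit fully connected
bypass runs alongside each stage to prevent information loss through the
sparse masks; `[Y4, bypass]` feeds a dense head (4 × 128 units with
batch-norm and dropout 0.7), a 20-unit bottleneck, concatenation of
demographic covariates (age, sex, education, APOE4, plasma p-Tau181), and a
linear output.  Masks come from a selection pipeline: genotype QC (missing
rate, MAF, Hardy-Weinberg exact test), per-SNP linear-regression scans with
Bonferroni control intersected across all cognitive tests, ±1 Mb window
linking, strand-aware TSS200/TSS1500 promoter mapping, hypergeometric GO
enrichment, and pruning of cross-layer orphans.  Everything — forward
model, backpropagation, DeepLIFT Rescale attribution — runs on a small
numpy reverse-mode graph; see `docs/methods.md` for the full account.

## Worked example

Restricted-access cohorts are emulated by a synthetic generator that plants
SNP→CpG→expression→score cascades with known ground truth:

```python
import hinnlab as hl

cohort, truth = hl.simulate_cohort(hl.SimulationParams(seed=1))
sel   = hl.select_features(cohort, hl.QCThresholds())
masks = hl.build_masks(sel.relation_map, cohort.snp_annotations,
                       cohort.cpg_annotations, cohort.gene_annotations)
X = hl.prepare_model_inputs(cohort, masks, hl.ArchitectureConfig())
models, metrics = hl.train_model(
    lambda s: hl.build_variant(hl.ArchitectureConfig(), masks,
                               X["demo"].shape[1], seed=s),
    X, cohort.scores["mmse"].to_numpy(), hl.TrainConfig(seed=18), "hinn", "mmse")
print(f"MMSE test MAE {metrics.mae_mean:.2f} ± {metrics.mae_sd:.2f}, "
      f"MSE {metrics.mse_mean:.2f} ± {metrics.mse_sd:.2f}")
```

On the seed-1 cohort (500 samples; 200 SNPs, 300 CpGs, 100 probes, 30 GO
terms; 5 planted cascades) the pipeline retains 4 SNPs, 30 CpGs, 15 probes
and 5 GO terms — 80% of the causal SNPs survive selection — and a
representative run prints

```
MMSE test MAE 3.90 ± 0.03, MSE 23.22 ± 0.52
```

against an MMSE variance of ≈53: the network explains roughly half the
score variance, and the biologically wired model beat its
randomized-connectivity ablation in 3 of 3 repeats (randomized mean MSE
29.4, +26% degradation).  DeepLIFT attribution ranks the planted causal
features at mean within-layer percentile ≈80 versus ≈42 for null features,
and 4 of the 5 planted cascades appear as complete SNP→CpG→probe→GO paths
in the top-10 Sankey export.  The p-Tau proxy correlates with the scores in
the expected directions (MMSE ρ ≈ −0.34, ADAS11 ρ ≈ +0.32).

The same pipeline is scriptable from the shell:

```bash
hinnlab simulate  --config configs/e2e.yaml --out-dir d/cohort --seed 11
hinnlab select    --cohort-dir d/cohort --out-dir d/select
hinnlab train     --cohort-dir d/cohort --select-dir d/select --out-dir d/train
hinnlab ablate    --cohort-dir d/cohort --select-dir d/select --out-dir d/ablate --variants all
hinnlab explain   --cohort-dir d/cohort --select-dir d/select \
                  --checkpoint-dir d/train --out-dir d/explain --top-k 10
hinnlab correlate --cohort-dir d/cohort --select-dir d/select \
                  --explain-dir d/explain --out-dir d/corr
```

emitting TSV/JSON throughout: `relation_map.json`, `qc_report.json`,
`associations.tsv`, `metrics.json` (mean ± sd over repeats),
`ablation_metrics.json`, `attributions.tsv`, `sankey.json`, and the
Table-style correlation TSVs.

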