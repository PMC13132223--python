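# organnet

Cross-organ gene co-expression network conservation and minimal
rejection-signature analysis.

## The problem

Allograft rejection is usually studied one organ at a time, with
organ-specific biomarker panels that need separate validation and clinical
workflows. If the core of the alloimmune response is conserved across
transplanted organs, a single transcriptomic framework — and a single small
gene panel — could monitor rejection in liver, kidney, heart and beyond.
`organnet` implements that analysis as a tested, reusable library for
transcriptomic data (log2 gene-by-sample matrices with binary
normal/pathological annotations):

1. **Per-organ co-expression networks.** Genes are filtered (low mean
   intensity removed, top 25% by variance retained), all pairs are
   correlated with Spearman's ρ, p-values are BH-adjusted, and an edge is
   kept iff |ρ| > 0.8 and q ≤ 0.05. Topology metrics (density, clustering
   coefficient, components) characterize each organ's network.
2. **Gene modules.** Each network is partitioned with Leiden community
   detection (weighted modularity, resolution 0.2).
3. **Cross-organ conservation.** Modules from different organs are linked
   by Jaccard similarity when their gene overlap is significant (one-sided
   hypergeometric test, pooled BH). Connected components of this module
   similarity network are *conservation groups* (BC1, BC2, …); module
   triples with all three pairwise links are *triangle motifs*, scored by
   fold enrichment `observed / E[overlap]` with `E[overlap] = n₁·n₂/N`.
4. **Module activity.** The *module eigengene* — PC1 of the z-scored module
   submatrix — gives one activity score per sample; Welch's t-test (and
   Welch's ANOVA plus pairwise Welch tests with BH for multi-group designs)
   quantifies class separation without assuming equal variances.
5. **Minimal signatures.** Conserved genes feed three classifiers (random
   forest with 100 trees, linear SVM, lasso-logistic with λ = 0.1) under
   stratified 10-fold CV (ACC/AUC ± sd, 95% CI = estimate ± 1.96·SE).
   Built-in, permutation and exact Shapley importances from the
   best-performing family are min-max normalized and averaged into a
   consensus ranking; a feature-count sweep locates the plateau where a
   small panel matches the full signature.

A synthetic multi-organ generator with planted ground truth (block-correlated
modules driven by latent factors, class-dependent activity shifts, partial
cross-organ membership overlap, low-variance background genes) makes every
stage testable end to end without downloading data.

## Worked example

`examples/05_classification_and_ranking.py` classifies one synthetic organ
cohort on its planted immune signature plus matched background genes, then
derives the consensus ranking and the sweep:

```
random_forest: ACC 0.944 +/- 0.062, AUC 0.993 +/- 0.016 [95% CI 0.983 - 1.000]
linear_svm: ACC 0.956 +/- 0.030, AUC 0.995 +/- 0.011 [95% CI 0.988 - 1.000]
l1_logistic: ACC 0.963 +/- 0.032, AUC 0.995 +/- 0.008 [95% CI 0.990 - 1.000]

best family (1-SE rule): random_forest
top-20 consensus genes: 20/20 are planted signature genes

feature sweep (AUC plateaus around 20 genes):
 n_features  acc_mean  acc_sd  auc_mean  auc_sd
          1     0.750   0.102     0.854   0.084
          5     0.950   0.040     0.992   0.018
         20     0.950   0.049     0.993   0.012
        100     0.956   0.042     0.993   0.014
```

All three families separate pathological from normal biopsies almost
perfectly (AUC ≈ 0.99); every one of the top-20 consensus-ranked genes is a
planted signature gene, and a 20-gene panel performs within 0.001 AUC of the
full 100-gene set — the plateau that motivates a minimal signature. The
other scripts in `examples/` walk through simulation, network construction,
module detection, conservation analysis, eigengene statistics, and the full
pipeline (`06_full_pipeline.py`, equivalent to
`organnet run-all --simulate --outdir out/`).

## Command line

A thin CLI wraps the library: `simulate`, `preprocess`, `network`,
`modules`, `conserve`, `eigengene`, `dge`, `classify`, `validate`, `rank`,
`sweep`, `run-all` (see `organnet --help`). All tabular output is
deterministic TSV; nested reports are JSON; a run manifest records config,
seeds and input digests.

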