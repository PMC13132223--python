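# Methods

This note documents the models, statistics and design choices behind
`organnet`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and where the genuinely open
design decisions were settled.

## Synthetic multi-organ generator

The generator (`organnet.simulate`) emulates the statistical structure of
RMA-processed transplant-biopsy cohorts without reproducing any real data:
several organ cohorts over a shared gene namespace, imbalanced
normal/pathological classes, block-correlated gene modules whose activity
shifts with pathology, partial cross-organ overlap of corresponding module
memberships, and a majority of low-variance background genes (the overall
gene-variance distribution is right-skewed: most genes sit near the noise
floor, module genes well above it).

**Model.** One latent factor per module. For gene *g* in module *m* and
sample *s*:

    x_gs = baseline_g + λ_g · f_m(s) + ε_gs

with `f_m(s) ~ N(0,1) + d·1[s pathological]`, loadings `λ_g ~ U(0.8, 1.0)`,
noise `ε ~ N(0, 0.5²)` and baselines `U(4, 12)` log2 units (microarray
intensity range), drawn once per gene id and shared across organs so mean
filtering behaves consistently between cohorts. Background genes are
baseline + noise only. The module mean class difference converges to
(mean λ)·d, and within-module correlations are governed by
λᵢλⱼ·Var(f) / √((λᵢ²Var(f)+σ²)(λⱼ²Var(f)+σ²)).

**Defaults (the study conditions).** Three organs, 2000 genes per organ,
100 normal / 60 pathological samples, eight planted modules of sizes 20–60
with cross-organ membership overlap 0.5, seed 42. All eight modules are
class-associated — six "immune" modules at effect d = 1.5, a 24-gene
"cell_cycle" module at d = 2.0 (the strongly upregulated proliferation
analog), and a "metabolic" module at d = 1.5. The class association of
every module is deliberate: with loadings in [0.8, 1.0] and noise sd 0.5, a
class-neutral factor has Var(f) = 1 and the *best possible* gene-pair
correlation is 1/(1+0.25) = 0.8 — exactly the edge threshold — so a null
module would be invisible to the network stage by construction. The
mixture variance added by the class shift (d²·p(1−p) ≈ 0.53 for d = 1.5 at
37.5% prevalence) lifts within-module correlations to ≈ 0.80–0.85, the
regime where |ρ| > 0.8 edges exist but are not saturated.

**What the generator does not emulate.** Probe-level structure, RMA itself,
batch effects, missing values, dropout, platform differences, correlated
factors between modules beyond the shared class shift, and gene-gene
correlation among background genes. Passing tests therefore demonstrate
that the pipeline recovers block-correlated, class-shifted structure under
realistic noise — not that it is robust to batch confounding or platform
artifacts.

## Preprocessing

Two label-blind filters, in fixed order. (1) Genes with mean intensity
strictly below the q-quantile of the gene-mean distribution are removed;
the cutoff is not a universal constant, so it is exposed as a parameter
(default q = 0.25, linear-interpolation quantile) and recorded in the
filter report. (2) The top fraction (default 25%) of remaining genes by
unbiased sample variance is retained; the count is `ceil(fraction · n)` so
any positive fraction keeps at least one gene, and ties break by input
order.

## Co-expression networks

All-pairs Spearman correlation (mid-rank ties; two-sided p from the
large-sample t approximation, accurate for the ≥ 100-sample cohorts this
targets), BH adjustment over the n(n−1)/2 upper-triangle tests, and the
conjunctive edge rule |ρ| > 0.8 AND q ≤ 0.05. Negative correlations are
kept (threshold on |ρ|) with the signed value stored as an edge attribute.
Constant genes get ρ = 0, p = 1 rather than an error (the variance filter
normally removes them). Isolated genes are not network members. The
q-threshold (0.05) is conventional and configurable; whether FDR filtering
precedes or accompanies the |ρ| cutoff is immaterial under the conjunctive
rule. Topology metrics: density 2E/(V(V−1)), unweighted average local
clustering (degree < 2 contributes 0), connected components by traversal.

## Module detection

Leiden optimization of resolution-parameterized weighted modularity
(configuration null model, edge weights |ρ|) at resolution 0.2, iterated to
convergence, deterministic for a fixed seed. Communities smaller than
`min_size` (default 10, chosen to keep modules large enough for downstream
set statistics; configurable) go to a remainder set. Module ids are
assigned by descending size (ties by smallest member id) so labels are
stable across runs.

## Cross-organ conservation

Every inter-organ module pair is scored by the Jaccard index and a
one-sided hypergeometric upper tail P(X ≥ k); BH is pooled over all pairs
across all organ pairs (a single test family). An edge requires q ≤ 0.05
and at least one shared gene. The background N for pairwise tests defaults
to the **union** of the two organs' network gene universes — conservative
against inflated significance when universes differ — with `intersection`
or a fixed integer as alternatives.

Conservation groups are connected components of the similarity network
restricted to ≥ 2 organs, labeled BC1, BC2, … by descending union gene
count. Triangle motifs are module triples, one per organ, with all three
pairwise edges. A triple's three-way overlap statistics follow the
intersect-two-then-test-against-the-third procedure: n₁ = |A∩B|, n₂ = |C|,
expected overlap n₁·n₂/N, fold enrichment = observed·N/(n₁·n₂), p from the
hypergeometric tail. The core A∩B∩C is identical under all three pairings;
the reported statistics follow a fixed pairing convention (default: the
third module is the one from the lexicographically last organ) and N
defaults to the third organ's network size. Pipeline-level subgroup
p-values are BH-corrected as one family.

## Eigengenes and testing

Module genes are z-scored across samples (unbiased sd; constant genes
excluded with a warning) and the eigengene is PC1 of the samples × genes
matrix via SVD, with variance explained = first squared singular value over
the total. The sign is fixed by non-negative correlation with the module's
mean z-profile, making the eigengene fully deterministic and giving group
comparisons a consistent direction: for an upregulated module,
Welch's t(normal, pathological) is negative. Eigengenes are computed per
organ on all samples (class labels play no role in the projection).

Welch's t (unequal variances, Welch–Satterthwaite df) is the two-group
test; Welch's ANOVA (F*, df₂ = 1/(3λ)) precedes pairwise Welch tests with
BH when there are more than two phenotype groups. Differential expression
is a per-gene Welch t with BH FDR and log2FC = mean(pathological) −
mean(normal); this is a deliberate surrogate for moderated-t approaches —
**no empirical-Bayes variance shrinkage is performed** — adequate for the
descriptive per-gene summaries it serves, slightly conservative at very
small sample sizes.

## Classification

Binary pathological-vs-normal, three families: random forest (100 trees),
linear SVM (C = 1, scored by the signed margin; rank-based AUC needs no
probability calibration), and lasso-logistic with λ = 0.1 in the
inverse-regularization convention C = 1/λ = 10. Features are standardized
inside each training fold for the linear families (no leakage); folds are
stratified (k = 10) and depend only on the labels and the seed. Accuracy
uses the 0.5 probability threshold (margin sign for the SVM); AUC is the
exact Mann–Whitney statistic with ties counted ½. Summaries are mean ± sd
across folds with 95% CI = mean ± 1.96·sd/√k, clipped to [0, 1]. External
validation trains one model on the pooled discovery cohorts and scores a
held-out cohort once, aligning features by gene id and imputing up to 20%
missing genes with training means.

## Feature importance and the sweep

Three complementary scores over a common feature universe:

- **Built-in**: impurity importances (forest) or |coefficient| on
  standardized features (linear families), from the best-performing family.
- **Permutation**: out-of-fold — within each CV test fold, each feature
  column is permuted (default 10 repeats) and the mean AUC decrease is
  averaged over folds; negatives floor at 0. Permuting within the held-out
  fold avoids the optimism of in-sample permutation.
- **Shapley**: exact attributions implemented in `organnet._shapley` —
  closed-form `φ_j = w_j(x_j − μ_j)` for linear decision functions and
  path-dependent polynomial-time tree attribution for forests (validated
  against brute-force subset enumeration; per-sample attributions sum to
  prediction − expected prediction to machine precision). Mean |φ| per
  feature is the score.

Each vector is min-max normalized to [0, 1] (the literal reading of a
"[0, 1] range"; an all-equal positive vector maps to 1, so a single-feature
model scores 1.0) and the consensus is the unweighted mean, with ties
broken by permutation score then gene id.

**Best-family selection.** The family with the highest mean CV AUC is used,
under a one-standard-error rule: families within one SE of the best are
treated as tied, and ties prefer the random forest for its richer built-in
importances. The exact-equality tie rule is degenerate when AUC saturates —
at AUC ≈ 0.99 a family can "win" by a fraction of one concordant pair per
fold, and a linear model selected that way spreads its coefficients across
blocks of near-duplicate correlated genes, diluting every individual
importance; the 1-SE band restores the intended preference without ever
overriding a clearly superior family.

**Multi-organ consensus.** Per-organ consensus scores are averaged across
organs before the final ranking (alternatives: `min`, `rank-mean`).
Averaging across cohorts suppresses cohort-specific coefficient noise while
genuinely informative genes score consistently — single-cohort rankings
from a linear model can be unstable in the p ≈ n regime.

The sweep re-runs stratified CV on the top-c consensus genes over a count
grid (keeping the original column order so the full-grid entry is identical
to a plain CV run) and reports ACC/AUC per count and cohort; on planted
data the curve plateaus near 20 genes.

## Pipeline, determinism, numerics

`run_pipeline` chains preprocess → network → modules → conservation →
eigengene/Welch → differential expression → classification → consensus
ranking → sweep, deriving the signature as the union of triangle-motif core
genes (falling back to the largest group's union, then all module genes)
when none is supplied, and writes deterministic TSV/JSON (`%.10g` floats)
plus a manifest of config, seeds, input digests and outputs; a single-organ
input skips conservation with a logged notice. Every stochastic step
(generator, Leiden, forests, CV folds, permutations) is seeded from the
config, so reruns are byte-identical. Degenerate inputs have defined
behavior throughout: empty networks yield empty-but-valid objects and
zeroed metrics, zero-variance genes are mapped or excluded as described,
both-empty set comparisons and single-class folds are errors.

The default test and acceptance runs use the generator's study conditions
(3 × 2000 genes × 160 samples); unit tests use a 400-gene, 64-sample
configuration where full scale adds nothing.

## Known limitations

- The Welch-t differential expression is not a moderated-t equivalent.
- The hypergeometric model treats gene sets as uniform draws; co-expression
  structure within the background makes it anti-conservative in principle
  (the shuffled-module null keeps the empirical false-edge rate at or below
  the nominal FDR on planted data).
- Functional enrichment (KEGG/Reactome/GO) is out of scope; gene panels are
  exchanged as plain text lists.
- The generator's single-factor blocks cannot probe hierarchical or
  overlapping community structure, and Leiden is run single-seed (no
  consensus clustering).
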