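# Methods

This note records the statistical model behind each stage, the default
parameters and why they hold their values, the scope of the synthetic-data
generator, and the numerical/design decisions a user should know before
trusting the output.

## 1. Synthetic data model

The generator emulates a whole-blood bead-array case–control experiment on
the log2 scale and returns raw intensities (`2^x`) so the QC stage's
quantile-normalize-then-log2 step applies exactly as it would to scanner
output.

Per probe *i* and sample *j*:

```
x_ij = b_i + s · e_ij,    b_i ~ N(baseline, 0.5²)
```

with `baseline = 7`, noise scale `s = noise_sd = 1`, and `e_ij` built from
up to four planted components:

- **Co-expression modules** (single-factor model). For a module with
  target within-group correlation `r`, member probes share one per-sample
  factor `f_j ~ N(0,1)`:
  `e_ij = sqrt(r_g) f_j + sqrt(1 − r_g) ε_ij`, with `r_g` the group's
  (case/control) target. The expected pairwise Pearson/Spearman
  correlation is then exactly `r_g`, so detection thresholds can be
  reasoned about analytically. A module planted with
  `preserved_in_replication=False` has its loading zeroed in the final
  third of each group's columns (the designated replication stratum,
  recorded in the truth tables); a non-positional random split cannot know
  which samples carry the structure, so non-preservation is made testable
  by column-order designation. The single-factor construction restricts
  `r` to [0, 1]: uniformly negative pairwise correlation is impossible for
  more than two genes (positive-semidefiniteness bounds r ≥ −1/(m−1)).
- **Differential expression**: a block of probes receives an additive
  case-group shift of `de_effect` (in units of `noise_sd`).
- **Sex-check probes**: the final `n_sex_probes` probes (annotated chrX,
  `is_sex_check_probe`) are shifted `sex_effect = 6` log2 units in males.
  Real sex-discriminating transcripts (XIST, chrY) separate by ~5–7 log2
  units; at lower separations a per-probe two-cluster predictor has
  non-trivial error and the ≥ 2-of-8 discordance rule would falsely
  exclude concordant samples.
- **Background latent factors**: every non-planted probe loads (random
  sign) on one of `n_background_factors = 5` shared per-sample factors at
  variance fraction `background_r = 0.1`. This mimics the continuous
  cell-composition/technical axes that dominate the leading principal
  components of real blood arrays. Without it, at scaled-down probe
  counts, degenerate directions (duplicate-pair noise, planted-module
  factors) become PC1/PC2 and the robust PC-outlier rule flags legitimate
  samples. At 0.1 the pairwise background correlation is ~0.1
  (`0.1^6 = 10⁻⁶` after soft-thresholding), invisible to module
  extraction, and identical in both groups, hence invisible to
  differential co-expression by construction.

QC defects are planted on top: outliers (+10 `noise_sd` global shift,
separating on PC1), low-RIN samples (RIN redrawn from U(4, 5.9)), and
duplicates (appended near-copy columns, σ = 0.02 `noise_sd`, sourced only
from clean samples — a copy of an outlier would inherit the flaw and be
excluded for the wrong reason). Every planted feature is reported in
`truth` (per probe: module, DE flag) and `truth_samples` (per sample:
duplicate/outlier/low-quality/replication-designate flags).

Covariates (sex, hypertension, smoking, familial history, leukocyte
differentials) are drawn with realistic case/control frequencies but no
planted expression association; they exercise the adjustment machinery
without confounding the planted signal.

## 2. Quality control

Sample filters run in a fixed order, and each exclusion carries the reason
of the *first* rule that hit, so the report accounts for every input
sample exactly once:

1. **Lab quality**: RIN < 6 or 260/280 < 1.8 (strictly below; a sample at
   the threshold is kept).
2. **PC outliers**: probes centered, SVD of the sample-space matrix;
   samples > 5 robust SDs (1.4826 × MAD) from the median on PC1 or PC2 are
   excluded. This is a deterministic surrogate for the visual PCA
   inspection of array workflows. Inside `run_qc` the decomposition uses
   autosomal probes only; with few probes the sex-chromosome shift would
   otherwise make PC2 the sex axis and flag one sex wholesale.
3. **Sex concordance**: each sex-check probe's intensities are split by a
   deterministic 1-D two-means; cluster labels are oriented by majority
   agreement with the reported sex; samples with ≥ 2 discordant probes are
   excluded.
4. **Duplicates**: Pearson r > 0.99 between samples; transitive groups
   keep the earliest column.

Probe filters follow (priority non-specific > non-autosomal (X/Y/MT) >
retired), then quantile normalization (every column mapped onto the
per-rank column means, ties averaged) and log2. Sample-level statistics
are computed on log2 of the raw intensities — variance-stabilizing without
changing the rank structure the later steps rely on. Leukocyte
differentials are compared case vs control with a tie-corrected,
continuity-corrected normal-approximation Wilcoxon rank-sum implemented
in-package because scipy returns NaN when all observations tie (the
degenerate case must report p = 1); scipy is the oracle on non-degenerate
inputs in the tests.

The discovery/replication split assigns floor(n/3) of each phenotype
stratum to replication.

## 3. Covariate adjustment

Two-step surrogate variable analysis: the protected primary variable
(case status) is regressed out of every probe by OLS; the leading left
singular vectors of the sample-space residual matrix are the surrogate
variables (orthonormal). With `n_sv="auto"` the dimension comes from
parallel analysis — 20 column-permutations of the residual matrix, keep
component k while its variance share exceeds the permuted 95th percentile
for component k. Known risk-factor adjustment is per-probe OLS
residualization; a rank-deficient design raises an error naming the
collinear columns, and the pipeline drops covariates that are constant
within a stratum (they carry no information there) with a logged warning.

## 4. Differential expression

Per probe, logistic regression of case status on the standardized probe
(per-SD effect sizes) plus covariates, fit by IRLS, Wald z test on the
expression coefficient. Separated, non-converged or constant probes report
p = 1 with `converged=False` rather than crashing or leaking an
anti-conservative p. BH-FDR controls multiplicity; the two-stage procedure
refits discovery hits (FDR < 0.05) in the replication set and re-applies
BH within that subset. A candidate-gene lookup Bonferroni-corrects over
the mapped probes only (α / n_tested).

## 5. Co-expression and CDC

Adjacency `a = |ρ_Spearman|^β` with β = 6 (the conventional unsigned
soft-threshold default; Spearman for robustness to intensity outliers).
Modules are branches of an average-linkage dendrogram of `1 − a` cut at
0.96, minimum size 30, labelled by the conventional palette in descending
size order (turquoise, blue, brown, …); smaller clusters become
"unassigned". The CDC test compares a module's mean gene significance
(−log10 DE p) to ≥ 1000 random same-size sets drawn from assigned genes,
`p = (r + 1)/(n + 1)`.

## 6. Differential co-expression

Per group `c = sign(ρ)|ρ|^β`; the signed form matters because a
correlation flipping sign between groups is a larger change than a decay
to zero. Pairwise change `d_ij = sqrt(0.5 |c_case − c_control|) ∈ [0, 1]`;
DC modules come from average-linkage clustering of `1 − d` with the same
cut (0.96) and size (30) defaults. A module's dispersion statistic is

```
D_s = sqrt( mean_{i<j} d_ij² )
```

tested by shuffling case/control labels (sizes preserved, module
membership fixed at the observed clustering — the selection step is part
of the observed statistic, not re-run per permutation, matching the
workflow this implements). `perm_index` counts null `D_s ≥` observed;
`p_emp = perm_index / n_perm`; Bonferroni over the m tested modules. An
exhaustive mode enumerates all label splits for small groups and is used
as the oracle for the sampled mode.

**Preservation**: the module's density (mean within-module `d` in the
replication network) and connectivity (correlation of intramodular
connectivity between discovery and replication) are each standardized
against random same-size gene sets; `Z-summary` is their mean and > 10
flags strong preservation. Two caveats, both enforced or documented:
a module may not exceed half the gene universe (the random-set null
degenerates), and the connectivity statistic is only meaningful when the
module is a modest fraction (≲ 15%) of the universe — when random sets
are largely module genes, their connectivity correlations become tight
and high, and a homogeneous single-factor module (whose intramodular
connectivity is uniform, so its own connectivity correlation is noise)
can receive an arbitrarily negative connectivity Z. At realistic
proportions the density term dominates and planted modules score
Z-summary ≈ 40–80.

## 7. Hub genes

The module's `d`-matrix is binarised by keeping within-module edges with
weight ≥ the 0.9 quantile of all within-module pairwise weights (boundary
ties all kept), restricted to the largest connected component. Per node:
degree, unnormalised betweenness, mean shortest-path length, local
clustering coefficient. One point each for top-20% degree, top-20%
betweenness, bottom-20% path length, bottom-20% clustering (ties at the
boundary included); score ≥ 2 marks a hub. Tie inclusion is deliberately
generous: on highly symmetric graphs (stars, complete graphs) every node
can qualify, which the code flags with a degeneracy warning.

## 8. Classification

Nearest shrunken centroids: standardized centroid offsets
`d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0))`, `m_k = sqrt(1/n_k − 1/n)`,
`s0 = median(s_i)`; soft-thresholding by δ shrinks genes to the overall
centroid and drops genes with zero offset in every class. Prediction by
the discriminant `Σ (x_i − x̄'_ik)² / (s_i + s0)² − 2 log π_k`, class
probabilities ∝ `exp(−δ_k/2)`. δ is chosen by stratified K-fold
cross-validation, taking the *largest* δ (fewest genes) at the minimum
error; ties in the discriminant resolve to the first (control) class. The
pipeline also scans the δ grid from most to least shrunken for the
smallest gene set meeting a replication-error ceiling.

## 9. Pipeline and determinism

One global seed deterministically derives a per-stage seed via
CRC32(stage name) folded into a `SeedSequence` (all derived seeds
< 2³¹), so any stage can be re-run in isolation. `report.json` contains
no timestamps and is byte-identical across reruns of the same config;
wall-clock timings go to `run.log` only. Hub analysis runs only on
modules passing both gates (permutation `p_bonf < 0.05` *and* preservation
`Z-summary > 10`).

## Default parameters

| parameter | default | rationale |
|---|---|---|
| β (soft threshold) | 6 | conventional unsigned-network default; scale-free-ish adjacency without erasing moderate correlations |
| cut height | 0.96 | static cut near the dendrogram top; pairs need `|ρ|^6 ≳ 0.04` (ρ ≳ 0.58) to enter a module |
| min module size | 30 | modules below this are noise-prone for permutation and preservation inference |
| DC permutations | 10 000 | resolves p_emp to 10⁻⁴, matching the reported permutation indices |
| preservation permutations | 200 | Z-scores need moments, not tail quantiles |
| RIN / purity | 6 / 1.8 | standard array-QC thresholds |
| PC outlier k | 5 robust SD | conservative; only gross outliers excluded |
| duplicate r | 0.99 | biological replicates of distinct subjects stay below this on array data |
| edge quantile | 0.9 | keeps the strongest decile of within-module edges |
| hub fraction | 0.2 | top/bottom quintile per criterion, score ≥ 2 of 4 |
| CV folds / δ grid | 10 / 30 linear | standard for n ≈ 150 discovery samples |

Problem sizes in the defaults (119/118 samples, 34 135 probes) describe
the emulated study design; all analyses scale to arbitrary sizes and the
tests run on far smaller configurations.

## Limitations

- The generator's modules are single-factor and homogeneous: no hub
  structure is planted, so hub *identities* cannot be scored against
  truth, only the scoring machinery itself (tested against hand-worked
  graphs and brute-force oracles).
- Expression is Gaussian on the log2 scale; no heavy tails, no
  intensity-dependent variance, no probe cross-hybridization.
- The permutation test conditions on the observed module assignment;
  cluster-then-test selection effects are controlled empirically (null
  false-detection rate is part of the acceptance suite) rather than
  analytically.
- The connectivity preservation statistic is uninformative for
  factor-homogeneous modules (see §6); density carries the signal.
- Logistic DE treats probes independently; no empirical-Bayes variance
  moderation.
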