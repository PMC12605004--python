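# Methods

This note documents the models and procedures `omicnet` implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for reproducing
its outputs.

## Data model and preprocessing

Abundance tables are samples × features with an explicit missingness mask.
Protein features come from an aptamer platform: strictly positive relative
fluorescence units (RFU), complete, with feature identity defined by
`display_name|platform_barcode` — two reagents targeting the same protein are
two features, never collapsed. Metabolite features arrive "scaled imputed"
style: per-feature median scaled to 1, missing cells allowed.

QC follows the platform conventions. Metabolites missing in strictly more
than 20% of samples are removed (a feature missing in exactly 20% is kept).
Remaining missing cells are filled with the per-feature minimum of the scaled
observed values; scaling precedes imputation because low-abundance censoring
is the assumed missingness mechanism and the minimum is only meaningful on
the common scale. The order is exposed as a switch
(`scale_and_impute(order=...)`) for sensitivity analysis.

All downstream statistics operate on natural-log abundances for both omic
blocks (`preprocess_proteins`, `preprocess_metabolites`, each with `log=`
flags). Whether the original analyses logged the platform readouts is not
documented anywhere we could verify, so this is the package's own choice:
linear models on raw lognormal abundances are mis-specified, and on the
synthetic world the raw metabolite scale attenuates a planted Cohen's d of
1.2 to roughly 0.4–0.9 purely through skew.

## Differential abundance

Per feature, ordinary least squares of abundance on a phenotype indicator
(one RA subgroup vs. controls) with covariates sex, age, BMI, smoking history
(never/former vs. current; samples with unknown history are excluded from
adjusted models), and three medication flags (prednisone, bDMARD, csDMARD).
The phenotype coefficient's two-sided t-test p-value is paired with an
**unadjusted** Cohen's d between the two groups (pooled-SD convention):
strict calls need p < 0.01 and |d| > 0.5, relaxed calls (used to feed
enrichment) p < 0.05 and |d| > 0.5. An adjusted-d option (residualizing on
the covariates first) exists but is not the default, because the
p-plus-plain-d pairing is the analysis convention this package reproduces.
No multiple-testing correction gates the calls; Benjamini–Hochberg q-values
are emitted as an extra column.

Covariate columns that are constant in the analyzed subset — the medication
flags in a treatment-naïve rerun, for instance — are dropped automatically.
The treatment-naïve subset is all samples with none of MTX, prednisone,
bDMARD or csDMARD exposure (controls always qualify).

A design point worth knowing: because controls are never medicated, the
medication covariates are strongly collinear with the phenotype indicator
(variance inflation ≈ 2 in the synthetic world even with correlated
co-prescription). Adjusted power is therefore intrinsically below the
orthogonal-covariate textbook value; it is recovered in realistic worlds
where covariates genuinely explain feature variance, since adjustment then
also shrinks the residual.

The OLS core is a vectorized least-squares solve shared across all features
(one design, thousands of responses); statsmodels is used as an independent
oracle in the tests, not as the implementation.

## Clinical correlation

Spearman ρ (average ranks for ties) between each feature and ESR / CRP /
DAS28-CRP, computed inside each RA subgroup on pairwise-complete
observations, with the two-sided t-approximation p-value. Exactly monotone
pairs are reported with p = 0. Constant features or markers yield a flagged
undefined ρ, not an exception. Cross-subgroup concordance classes: a subgroup
"passes" at |ρ| > 0.4 and p < 0.05; both pass with one sign → concordant;
both significant with opposite signs → opposite; one passes while the other
is non-significant → subgroup-specific. Group-mean Z-scores standardize each
feature's three group means to mean 0, SD 1 (sample SD across the three
means; the three-point SD convention matters and is fixed here).

## Enrichment

One-tailed over-representation of a hit set against annotation terms
intersected with a declared universe: p = P(X ≥ k) with
X ~ Hypergeometric(N, K, n). The EASE-style variant computes P(X ≥ k−1)
(floored at zero), discounting terms supported by a single overlapping hit.
Both p-values are always reported; `mode` selects which drives the enriched
flag (default: standard), together with a minimum-overlap floor of k ≥ 2.
The default universe is all features that passed QC on the platform.

## Network inference

Meinshausen–Bühlmann-style neighborhood selection with an elastic-net
penalty. Every omic feature in turn is the response; predictors are all
other features plus covariate columns and the three one-hot phenotype
indicators (clinical columns are never responses). The penalty is
parameterized as mixing α ∈ {0.1, 0.3, 0.5, 0.7, 0.9} (the L1 share; the
λ₁ + λ₂ = 1 constraint maps onto this form) and overall strength over a
15-point log-spaced path down to 5% of the critical penalty. Hyperparameters
are chosen by 10-fold cross-validation of RMSE, with predictors standardized
**inside each training split** so validation rows never leak into the
scaling. The mixing value is taken at the CV minimum; the penalty within the
winning mixing follows the `1se` convention (largest penalty within one
standard error of the CV minimum — the default extraction of the glmnet
package this procedure descends from), with plain CV-min available as
`selection_rule="min"`. CV-min extraction over-selects substantially at this
scale (about 40% spurious edges in block-structured worlds); the 1se rule
restores the sparsity the procedure is meant to deliver.

The per-response neighborhoods merge into one undirected, unweighted graph
under the union rule: an edge exists if either endpoint selected the other.
Union rather than intersection is forced by the design — covariate and
phenotype nodes are predictors only, so intersection would erase every
feature–phenotype edge. An intersection option exists for feature–feature
sensitivity analysis.

## Diffusion

Random walk with restart on the column-normalized binary adjacency
(undirected edges walked both ways): p^{t+1} = (1−r) A′ p^t + r p⁰ with
r = 0.5, stopping when the L1 change drops below 1e-4 (both settable). The
seed distribution is uniform over the phenotype nodes. Mass reaching a
zero-degree column is redirected to the seed distribution, keeping scores a
probability vector; the iterative solution matches the direct linear solve
p = r(I − (1−r)A′)⁻¹p⁰ to L1 1e-6 on connected graphs. Top-N cuts rank only
biomolecule nodes (phenotype and covariate nodes are excluded before the
cut), break ties lexicographically by node ID, and attach the induced
subgraph.

## Classification

Stratified 5-fold CV over the three-group cohort: every fold's test set
holds an equal count per group (8/8/8 at 40 per group). Inside each training
fold, and using only its rows: network inference with training-label
phenotype nodes, RWR ranking, top-N feature cuts, and random-forest training
(500 trees, √p features per split, seeded per fold). Held-out rows are only
ever scored. Tasks: each RA subgroup vs. controls (16-sample test sets) and
pooled RA vs. controls (24-sample test sets, trained 64 vs. 32 without
re-balancing). Baseline selectors — none, ANOVA F, mutual information — run
on identical fold assignments so comparisons are paired.

Metrics: rank-based AUC (ties get half credit), confusion-matrix panel at a
0.5 probability threshold, F1 and MCC; ratio metrics with a zero denominator
are excluded from fold averaging. Reported values are taken at the
subnetwork size N with the highest mean test AUC. That best-N choice is
post-hoc (it peeks at test AUC across N); we mirror it because it is the
reporting convention being reproduced, and flag it here rather than hiding
it. A fully nested choice of N (an inner CV per fold) was considered and not
implemented — it multiplies the per-fold network-inference cost by the size
of the N grid; treat the summary at best N as an upper reporting bound and
the per-N fold table (always emitted) as the honest view.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, not disease
biology. Latent log-abundance per feature: baseline + one latent community
factor + planted group shift + covariate effects + Gaussian noise
(`noise_sd` 1.0). Defaults describe a matched 40/40/40 cohort; feature
dimensionality is scaled down about 25-fold (260 proteins + 40 metabolites,
preserving the ~7:1 block ratio) because per-feature cross-validated network
inference at full platform scale is not desk-feasible.

- **Correlation structure**: 30 latent factors, each feature loading on
  exactly one (loading ~ N(0, 0.8)) — correlated blocks of ~10 features,
  pathway-scale, giving network densities comparable (relatively) to real
  multi-omic graphs. A dense global-factor alternative was rejected: it makes
  every feature correlated with every other and network selection
  legitimately dense, which no real omics network resembles.
- **Planted effects**: group mean shifts specified as target Cohen's d on the
  latent log scale; the shift is d × total latent SD with the variance
  accounting covering factor, noise and covariate components, verified by
  Monte Carlo at n = 2000/group to land within ±0.1 of target.
- **Covariates**: matched across groups by default (no confounding), with
  demographics patterned on the cohort being emulated (70% female, age
  58 ± 10.5, BMI 29.5 ± 7, 6% current smokers, 3% unknown smoking).
  Nonzero covariate effects on features are the default (coefficient SDs 0.4
  for age/BMI/sex, 0.3 smoking, 0.2 per medication flag) — age, sex and BMI
  demonstrably drive plasma omics, and a generator without them would make
  covariate adjustment pure cost. Group-conditional covariate offsets
  (`confounding`) are available to construct confounded worlds.
- **Medications**: RA samples only. Co-prescription is modelled by a latent
  on-treatment state covering 67.5% of RA patients (anchored to the reported
  treatment-naïve sub-cohort of 26/80), with per-drug conditional
  prevalences preserving the marginal rates (MTX 51%, csDMARD 31%,
  prednisone 25%, bDMARD 21%).
- **Clinical markers**: ESR/CRP/DAS28-CRP are generated for RA samples as
  `marker_coupling` × the standardized mean of the planted features' latent
  signal plus noise; controls have missing markers, as in routine care data.
- **Missingness**: per metabolite, the lowest `missing_censor_frac` (default
  10%) of values are censored before median scaling — the MNAR mechanism
  minimum-value imputation presumes.
- Identical seeds give bit-identical cohorts.

What a green test on this world does **not** establish: instrument artifacts
(plate effects, drift), non-lognormal abundance families, nonlinear
covariate effects, correlated missingness across features, or biology beyond
mean shifts and block correlation. Cohort-specific published hit lists and
AUCs require the deposited cohort data and are out of scope.

## Numerical conventions

- Fisher exact (2×2 and r×c): full enumeration over fixed margins, two-sided
  p = sum of point probabilities ≤ the observed table's (with a 1e-7
  relative tolerance on the comparison); enumeration guarded at a table
  total of 10,000. Quartiles: linear interpolation (type 7). Kruskal–Wallis:
  tie-corrected H, χ² p on k−1 df; all-identical input returns a flagged
  p = 1.
- Elastic-net path: coordinate-descent tolerance 2e-3, 15 penalties,
  path floor at 5% of critical — runtime tradeoffs; CV-chosen penalties sit
  in the top decade of the path in all measured worlds.
- RWR: dense linear algebra (graphs here are ≤ a few thousand nodes);
  ranking ties broken by node ID.
- Random-forest hyperparameters are not pinned by the analysis convention
  being reproduced; defaults are 500 trees, √p features per split, per-fold
  seeds, all exposed in `TaskSpec`.
- Every stochastic step takes an explicit seed; pipeline manifests record
  config hash and seeds.
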