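# Methods

## The analysis model

`metabofp` analyzes a samples × metabolites abundance matrix from a
two-group (control vs case) study. The pipeline order is fixed and
enforced through a scale tag on the feature table:

    filter (missingness) → KNN impute → fold change (raw scale)
    → log2 transform → autoscale → statistics / clustering / SVM

Fold change is defined as the ratio of *arithmetic* group means on the
raw intensity scale, computed before any transformation; attempting to
compute it on log2 or autoscaled data raises a contract error. The
matrix handed to every downstream method is log2-transformed and
autoscaled (per-metabolite z-scores with ddof = 1).

### Missingness filter

A metabolite is discarded when its missing proportion is ≥ the threshold
(default 0.5, inclusive — "50% or more") in *either* group. The filter
is idempotent and never changes the sample set.

### KNN imputation

Each missing cell is replaced by the mean of the k (default 10) nearest
samples' observed values for that metabolite. Neighbor distance is
Euclidean over co-observed values after per-metabolite standardization,
rescaled by `p / n_co-observed` (the NaN-aware Euclidean convention) so
samples with different overlap sizes are comparable. Only samples with
the target metabolite observed are donor candidates; the effective k
shrinks when fewer exist, ties in distance break by sample order, and a
cell whose every donor shares no observed metabolite falls back to the
metabolite's observed mean (recorded in the report). The k, metric and
orientation are this package's documented defaults — common
metabolomics-suite behavior — not values fixed by any single convention.

### Univariate statistics

Per metabolite, a two-sided two-sample t-test on the log2 data: Welch
(unequal variances, Welch–Satterthwaite df) by default, classical pooled
Student optionally — both are offered because small-cohort studies
commonly report each. q-values are Benjamini–Hochberg step-up
(`statsmodels`), and the joint default significance rule is *P* < 0.05
and *q* < 0.10. A metabolite with zero variance in both groups reports
t = 0, p = 1 with a degenerate flag. `summary_stat_ttest` computes the
same tests from published group summaries (mean, SD, n).

### Exploration

Hierarchical clustering uses Ward's minimum-variance criterion on
Euclidean distances (scipy; heights are √(2·ΔESS), merges
nondecreasing). PCA operates on the autoscaled matrix (equivalent to
correlation-matrix PCA), with a fixed sign convention: each loading
column is flipped so its largest-magnitude entry is positive. The
covariate screen regresses the first principal component score on each
(one-hot coded) covariate and reports R², flagging values above 0.5;
PC1 is this package's choice of discriminant score and is clearly
labelled as such.

### SVM fingerprint

Fifty independent stratified train/test splits: per class,
round(0.7·n) samples train (reduced if needed so every test set keeps
≥2 samples per class; the default 12/8 design yields 8+6 train and 4+2
test). Per split a soft-margin linear SVM with fixed cost C = 1 is
fitted — no inner tuning loop, since no tuning grid is specified for
this procedure; C is exposed as a configuration knob instead.
Preprocessing (imputation, autoscaling) is fitted once globally before
resampling, mirroring the stated order of the original workflow; this
leaks the test samples' scaling statistics into training, which is why
the permutation null below — subject to the same leakage — is the
correct baseline for the resulting AUC.

Test AUC is the Mann–Whitney rank statistic of the decision scores
(identical to the threshold-sweep ROC area; an all-equal score vector is
flagged and scored 0.5). ROC curves are averaged vertically: TPR is
interpolated at 101 fixed FPR grid points, averaged across iterations
with a per-point standard error. The headline AUC is the arithmetic
mean of per-iteration AUCs. On the default 4-control/2-case test sets
the per-iteration AUC has granularity 1/8.

Importance is the rank of |linear weight| within each iteration
(average-rank ties); the fingerprint is the per-metabolite mean rank
across iterations, ties broken by metabolite ID. The mechanism behind
an "importance score index" is not uniquely determined for linear SVMs;
|weight| on autoscaled data is the standard choice and is used here.

The permutation null shuffles the group labels independently before
*each* iteration, stratifies the split on the shuffled labels, and
repeats the full fit/score step; the summary is the 50 null AUCs, their
mean, and a normal-approximation 95% CI (mean ± 1.96·SD/√50). A
percentile CI would also be defensible; the normal form matches how such
intervals are usually printed and is symmetric around the mean by
construction.

## The synthetic-data generator

The generator emulates a 12-control vs 8-case study with 289
metabolites: 56 truly elevated and 56 truly decreased (112 differential),
17 metabolites with ≥50% missingness in at least one group, and the rest
null. Abundances are multiplicative lognormal,

    a_ij = base_i · r_i^[j is case] · 2^(ε_ij) / E[2^ε],   ε ~ N(0, σ_i²)

with σ in log2 units and base levels log-uniform over 10⁴–10⁷ (typical
MS intensity range). Dividing by E[2^ε] = exp((σ ln2)²/2) pins the
arithmetic control-group mean at `base_i`, so the designed case/control
ratio of arithmetic means is exactly `r_i`.

**Effect sizes.** Decreased metabolites draw ratios as reciprocals of
log-uniform values on [1.1, 4]; elevated ones draw from [1.1, 4]. Three
anchor metabolites carry fixed ratios 0.27, 0.71 and 1.14 — spanning the
strong-decrease / moderate-decrease / modest-increase regimes such
studies report — so fold-change recovery can be checked against known
values.

**Noise calibration.** Differential metabolites get σ from the
noncentral-*t* power relation: σ is chosen so that the two-sided
two-sample test at the design's sample sizes has 50% power at
significance level `target_p` — equivalently, the *median* p-value of
the designed effect equals `target_p`. The equation is solved by root
finding on the noncentrality scale (Welch df with equal group SDs; the
deep lower tail of the noncentral t underflows and is treated as zero).
Targets ≥ 0.5 are unattainable — two-sided power never falls below the
level — and raise an explicit error. Anchor metabolites use the quoted
p-values 2.4×10⁻⁴, 9.7×10⁻¹⁰ and 6.5×10⁻⁴; other differential
metabolites draw targets log-uniform over [10⁻¹⁰, 10⁻⁴], which gives
per-metabolite power ≈ 0.99+ at P ≤ 0.05 and makes the full count of 112
detectable true effects reproducible. Null metabolites draw σ uniform on
[0.2, 0.8].

**Missingness.** The 17 designated sparse metabolites (all null) lose
the ⌈0.5·n_group⌉ *lowest* cells of the affected group(s) — deleted
deterministically, emulating detection-limit censoring and guaranteeing
the filter removes exactly these 17 (289 → 272). Groups are affected in
a case-only / control-only / both rotation. Bernoulli (MCAR) deletion is
available for any other nonzero rate on custom specs. In the default
palette no retained metabolite has missing cells, so KNN imputation is a
no-op on the default dataset; the imputer is exercised by dedicated
tests on tables with sub-threshold missingness.

**Covariates.** Sex, litter and litter-linked birth dates are generated
independently of genotype, so the covariate screen flags only the group
label (their chance association exceeds R² = 0.5 in far under 1% of
runs).

**Determinism.** The same (design, specs, seed) triple yields
byte-identical CSV output; spec construction, value noise, and metadata
use separate child seeds of the design seed.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure — sample sizes,
effect-size range anchored to realistic ratios, noise levels consistent
with the quoted p-values, detection-limit missingness, nuisance
covariates. It does not simulate batch or drift effects, correlated
metabolite modules (features are independent given the design), raw
spectra, QC injections, or abundance-dependent variance beyond the
lognormal model. Passing tests therefore demonstrate correctness of the
pipeline's computations and its behavior under the intended study
design, not performance on any particular real cohort; feature
independence in particular makes classification easier than strongly
collinear real panels, which is one reason the perfect mean AUC is
expected here.

## Numerical choices and degenerate inputs

- Autoscaling flags columns whose SD is ≤ 10⁻¹² relative to their mean
  as constant (identical values can leave an O(eps) residual SD) and
  zeroes them rather than dividing by noise.
- log2 requires strictly positive values and names the offending cell.
- Ward is run via scipy's nearest-neighbor chain; equidistant merges
  resolve deterministically by input order.
- PCA requests beyond the rank bound truncate with a warning.
- BH q-values validate p ∈ [0, 1] and are order-preserving.
- All randomness flows from explicit seeds (`numpy` SeedSequence
  spawning for per-iteration streams); the classification stage is a
  pure function of (table, metadata, master seed).

## Problem sizes used in the test suite

The suite runs the full default study (20 × 289) wherever the design
matters, and scales repetition counts to keep the suite fast: 200
replicate studies for fold-change recovery and type-I error, 100 for
the two-clade separation rate, 40 pure-noise studies (20 SVM iterations
each) for null calibration, and 10,000-sample groups for moment-recovery
checks. These sizes give Monte-Carlo standard errors well inside the
asserted tolerances.

## Known limitations

- The estimator `mean(case)/mean(control)` is slightly biased upward at
  small n (E[X̄/Ȳ] > r); at the large calibrated noise of the
  strongest-decrease anchor this amounts to a few percent and is
  reported as-is.
- With only two test-set cases per split, per-iteration AUC is coarse
  (granularity 1/8); inference rests on the 50-iteration average and the
  permutation null, not on single splits.
- Global (pre-split) autoscaling is the faithful reproduction of the
  workflow but is not leakage-free; users wanting fold-safe estimates
  should rescale within training folds — the honest comparison here is
  against the equally leaky permutation null.
- The covariate screen's R²-against-PC1 statistic is a reasonable but
  non-unique operationalization of "covariate correlates with the data".
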