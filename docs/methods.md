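# Methods

This note documents the models, defaults and numerical choices behind
the package, and what the synthetic generators do and do not emulate.

## The triplot object and workflow

The unit of analysis is the triplot object (TPO): exactly one
latent-variable (LV) model plus ordered, named correlation and risk
blocks. `add_corr` / `add_risk` return a new TPO (the input is never
mutated) and preserve insertion order, which drives plot stacking.
Blocks are aligned to components positionally (block row *i* ↔
component *i*), validated by count; component names are stored in the
manifest for human checks. A TPO serializes to a directory of
tab-delimited tables plus a JSON manifest — inspectable, diff-able and
language-neutral — and round-trips within 1e-12 on all matrices. One
LV model per TPO: analyses comparing, say, PCA and PLS use two TPOs.

## Layer 1 — latent-variable models

**Preprocessing.** Default for both fitters is column centering and
unit-variance scaling (sd with n−1 denominator): metabolomics features
sit on heterogeneous intensity scales and unscaled PCA would be
dominated by the loudest channels. Zero-variance columns are an error
when scaling; missing values are rejected outright — imputation is a
separate modeling concern and silently imputing inside a fitter would
hide it.

**PCA** is computed by full SVD (via scikit-learn) on the centered
matrix; loadings are orthonormal, scores = X·loadings, and the
explained-variance share of component *k* is var(score_k) divided by
the total column variance. Requesting more components than the matrix
rank is an error that reports the attained rank.

**Sign convention.** SVD signs are arbitrary, so each component is
flipped to make its largest-absolute loading positive. This makes plot
orientation reproducible across platforms and re-runs.

**PLS** is the univariate/multivariate NIPALS algorithm with deflation
(tolerance 1e-10, max 500 inner iterations; non-convergence reports
the component index). The model stores x-scores, x-loadings, the
weight matrix W and y-loadings C (prediction uses
B = W(PᵀW)⁻¹Cᵀ). Explained variance is reported for X (used by the
triplot axis labels); the y-variance fractions sit in `meta`, since
either convention is defensible and the display needs the X one.

**Component count.** `pls_cv` runs repeated k-fold cross-validation
(stratified on binary y), standardizing within training folds, and
recommends the smallest component count whose mean RMSE is within one
sd of the global minimum (one-SE rule). This is a deliberately simple
stand-in for heavier nested/repeated double cross-validation schemes,
which are out of scope.

**Factor analysis** is not shipped; any external scores/loadings pair
(FA, O-PLS, anything) enters through `make_tpo`, which accepts exactly
that contract.

## Layer 2 — correlations

`make_corr` computes Pearson, Spearman or Kendall correlations per
LV × exposure cell with pairwise-complete deletion (maximizing per-cell
n; the per-cell sample size is recorded in `n_used` for transparency).
p-values are the standard tests: t approximation with n−2 df for
Pearson/Spearman, normal approximation for Kendall. A constant
exposure yields a NaN cell and a warning, not an error, so one
degenerate food column cannot kill a 17-column block.

`partial_corr` residualizes both the score and the exposure on the
covariates (plus intercept) by least squares and correlates the
residuals; the Spearman variant rank-transforms (average ranks for
ties) *before* residualizing — one of several partial-Spearman
definitions in the literature, recorded in block metadata. Degrees of
freedom are n − 2 − (number of covariates). An empty covariate set
short-circuits to `make_corr` exactly. Rank-deficient covariate
matrices are rejected with the collinear columns named.

Significance filtering defaults to per-cell p < 0.05 with no
multiplicity adjustment — matching the convention that display filters
describe "significantly correlated" exposures unqualified — with
Benjamini–Hochberg step-up available as an option applied across the
whole block.

Two named adjustment-set presets mirror the worked examples: the
matched-study correlation adjustment (case status, gender, age, BMI,
smoking, education, physical activity) and the risk-model adjustment
(BMI, smoking, education, physical activity, total energy intake).
They differ — energy intake appears only in the latter — and the
package ships both as-is rather than harmonizing them; adjustment sets
are always fully user-specified.

## Layer 3 — risk associations

All estimates default to **per-SD scaling** of the score predictor
(OR or beta per 1-SD increase in the LV score): component scores are
unitless, so the per-SD convention is what epidemiologists report.
Raw-scale estimates are available via `scaling="raw"`; for logistic
models the two are linked exactly by OR_per_sd = OR_raw^sd.

- `crude_lr`: maximum-likelihood logistic regression (Newton/IRLS,
  tolerance 1e-10, max 100 iterations) through statsmodels; OR =
  exp(β), Wald 95% CI with z = 1.96 (configurable), Wald p.
- `crude_clr`: conditional logistic regression for matched sets
  (statsmodels `ConditionalLogit`, Newton with tolerance 1e-12, which
  the oracle tests require). Outcome-concordant sets contribute
  nothing and are counted as dropped; no informative set, or a score
  constant within every set, is an identifiability error. Matched sets
  are capped at 10 members — desk-scale exactness without
  approximation machinery; larger sets are rejected.
- `linear_beta`: OLS with t-based 95% CI for continuous intermediate
  risk markers.
- `adjusted_fit`: the same estimators with covariates as additional
  linear predictors; the reported row always refers to the score
  coefficient. Zero covariates reduce bit-identically to the crude
  fit. For CLR, a covariate constant within all sets is rejected
  (absorbed by matching).

**Separation** is declared when |β| exceeds 15 on the logit scale or
the optimizer fails; the error advises a penalized fit, which is
deliberately not implemented (no Firth/penalized logistic, no survival
fitting). Externally computed hazard ratios enter as (estimate, ci_low,
ci_high, p) tuples via `risk_block_from_fits(scale="ratio")`.

## Synthetic studies

The generators define transparent latent-factor models whose
*qualitative* behavior matches the two study designs they emulate; no
attempt is made to reproduce any real cohort's numeric distributions,
only structure, dimensions and association directions.

**Matched T2D study** (default 500 pairs = 1000 rows; 11/31/17
columns). Each subject carries two latent diet factors — F1 "healthy
Nordic pattern", F2 "unhealthy pattern" — drawn bivariate normal with
correlation −0.3 (healthy and unhealthy eating compete). Fifteen FFQ
food items are linear mixtures of (F1, F2) plus noise (sd 0.8),
quantile-discretized into 8 ordinal categories (which is what makes
the Spearman/partial-Spearman pathway meaningful); two composite
diet-index columns are weighted sums of the nine index foods. The 31
metabolites are continuous log-scale mixtures — 21 loading F1, 10
loading F2, signs mostly positive — with noise calibrated per column
so the communality (variance share from the latents) is 0.4, a
realistic figure for plasma metabolomics that keeps recovery
nontrivial. Pairs share gender and differ by at most 2 years of age;
the case within each pair is drawn from the conditional logistic model
with log-odds (0, +0.5) on (F1, F2), so the unhealthy factor carries
the risk and conditional-logistic fits on the true F2 recover
OR = e^0.5 with nominal coverage. Baseline covariates (BMI, smoking,
education, physical activity, energy intake, two fillers) are weak
functions of the factors plus noise.

**Cross-sectional study** (default 300 rows; 11/20/11 columns). Two
independent factors — G1 "adiposity / meat & refined grains", G2
"seafood / omega-3". Eleven ordinal FFQ foods mix the factors; 14 of
20 metabolites load G1 and 6 marine-lipid-like columns load G2
(flagged in the truth metadata). The 9 clinical traits are linear in
the factors: BMI, liver enzymes (GGT/ALT/AST), glucose, triglycerides,
total and LDL cholesterol increase with G1, HDL decreases, and the
liver enzymes decrease with G2 — so PCA PC1 of the metabolites tracks
BMI and the enzyme panel by construction.

What the generators do **not** emulate: assay batch effects, missing
data, skewed/zero-inflated intensities, nonlinear exposure–factor
relationships, and real food-intake marginals. Tests passing on these
data therefore validate the *machinery* (estimators, containers,
filters, rendering) and the recoverability of known effects, not
performance on any particular real cohort.

## Visualization

`check_tpo` renders all components × (every exposure + one column per
risk block) as a diverging heatmap clipped at ±1; risk columns show
log(estimate) (ratio scale) or raw beta (linear), rescaled to the
block's max |value|; cells significant at `corr_alpha` are starred.
The numeric table behind the figure is returned for testing.

`triplot` geometry: loadings and correlation arrows share the center
panel but use separate scales — loadings are axis-scaled to their max
absolute value, correlations are fixed to the unit circle — with both
scales printed, because loading and correlation magnitudes are not
comparable quantities and a shared scale would imply they are. Risk
markers sit on margin strips parallel to each displayed component's
axis (per-component scalars are not 2-D points). Default filters:
loadings shown when |loading| > 0.25 on either displayed component;
exposures shown when significantly correlated (p < `corr_alpha`,
default 0.05) with either component, or listed in `always_show`, or
`show_all_exposures` is set. Label collisions are resolved by a
deterministic greedy displacement ordered by glyph magnitude (ties
broken by label), so identical inputs give identical output. Every
rendering returns a layout report listing each glyph's kind, label and
untransformed data coordinates; tests assert a bijection between
glyphs and filtered TPO entries rather than comparing images.

## Numerical choices and problem sizes

- NIPALS: tol 1e-10, max_iter 500; conditional/unconditional logistic:
  Newton, tol 1e-12/1e-10; Wald z = 1.96 throughout (no profile
  likelihood).
- Oracle agreement asserted at 1e-10 (PCA/SVD, partial-correlation
  equivalences), 1e-8 (NIPALS identity, paired-difference logistic),
  2e-4 (conditional-likelihood grid search at step 1e-4), 1e-3
  (2×2 closed-form OR/Woolf CI).
- Simulation-based suites use fixed seeds: the trivariate-Gaussian
  partial-correlation check at n = 5000; matched-pair parameter
  recovery at β ∈ {0, 0.3, 0.7} with 500 pairs × 200 replicates
  (mean bias < 0.05, Wald coverage within [0.92, 0.98]); generator
  recovery over 50 seeds (CI covers the true OR in ≥ 90%); the
  permutation-null recoverability check runs at 150 pairs × 30
  permutations × 20 seeds, sizes chosen to keep the default suite
  fast while leaving the checks well-powered.
- The two-factor cross-validation fixture uses two variable blocks
  with deliberately different communalities, because with autoscaled
  columns and a univariate response the predictive Krylov subspace
  only genuinely requires a second component when the relevant
  covariance eigenvalues differ.

## Known limitations

- No polychoric/polyserial correlations for ordinal exposures;
  Spearman is the supported rank pathway.
- No factor-analysis fitter, no O-PLS or sparse variants, no repeated
  double cross-validation; no Cox fitting (ingestion only).
- Partial Spearman is rank-then-residualize; other definitions
  (residualize-then-rank, Spearman of residual ranks) can differ
  slightly in small samples.
- The matched-set conditional likelihood is exact but capped at 10
  members per set.
- The composite figure states its own geometry (separate scales,
  margin strips); it does not claim pixel fidelity to any other
  implementation's arrangement.
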