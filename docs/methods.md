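# Methods

This note documents the statistical machinery in `ashazard`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real survey data.

## Exceedance models

The dependent variable is always an exceedance indicator: 1 iff a well's
arsenic concentration is *strictly* greater than a threshold (a value
exactly equal to the threshold is classed low). Six thresholds are
modelled by default — 10 µg/L (the WHO provisional guideline) and 5, 4, 3,
2, 1 µg/L, a ladder that resolves the low-concentration range where most
survey values fall. Each threshold gets its own logistic regression

  P(y = 1) = 1 / (1 + exp(−(β₀ + β₁x₁ + ⋯ + βₙxₙ)))

on z-scored covariates. Normalization statistics are computed once on the
full cleaned dataset, not per split, so coefficients averaged over many
resampled fits share one scale; the alternative (per-split statistics)
would make averaged coefficients incommensurable. The stored statistics
are re-applied, never re-estimated, when evaluating a model on a predictor
grid.

## Screening

For each threshold, repeated over `n_repeats` (default 1000) stratified
80/20 splits, each variable is tested univariately by the likelihood-ratio
test of the one-covariate logistic model against the intercept-only model
(χ², df = 1, or the indicator count for a categorical block); variables
with mean p < 0.05 survive. Multicollinearity among the surviving
*continuous* variables is then measured by the variance inflation factor
VIF = 1/(1−R²) of each variable regressed on the others, and filtered
iteratively: while the largest mean VIF exceeds 10, that variable is
dropped and the means recomputed, so the survivors' final VIFs are all
≤ 10 simultaneously. Categorical indicators are exempt from VIF.

Two R² variants are available for the VIF. The default is the classical
coefficient of determination of the auxiliary linear regression. The
alternative `deviance` variant computes R² = 1 − exp(−D/n) with D the
likelihood-ratio statistic of the auxiliary regression; for a Gaussian
auxiliary model D = n·ln(TSS/RSS), so 1 − exp(−D/n) = 1 − RSS/TSS and the
two variants coincide algebraically. Both are exposed because the
deviance-based pseudo-R² is how the formula is sometimes quoted; nothing
in the pipeline depends on the choice.

## Ensemble stepwise selection and gating

Run i (seeded `base_seed + i`, so the ensemble is a pure function of one
seed) draws a fresh stratified split and runs both-direction stepwise
selection minimising AIC = 2k − 2 ln L, starting from the full screened
model (configurable to a null start; the full start makes the first moves
removals, which is the natural direction when screening has already
discarded clearly irrelevant variables). Ties in AIC break toward fewer
variables, then lexicographically, making the search deterministic. The
selected model is then scored on the held-out 20% with the
Hosmer–Lemeshow test — records sorted by predicted probability, ten
near-equal decile-of-risk groups, statistic Σ (O−E)²/(E(1−E/m)), χ² with
g − 2 = 8 df — and the run passes iff p > 0.05. Degenerate groups (E = 0
or E = m) have their denominator floored at 1e−10 and are flagged.
Non-convergent fits (separation) are tallied separately and excluded.

Passing runs are grouped by their unordered variable combination.  Within
each combination, intercept and coefficients are averaged (with standard
deviations reported), the held-out AUC is averaged across runs, and a
whole-data AUC is computed once from the averaged coefficients. The final
model is the combination with the largest *mean held-out* AUC (ties:
larger occurrence count, then fewer variables, then lexicographic); the
whole-data AUC is reported alongside because the two orderings are
typically very close and some users prefer one or the other.

ROC curves sweep every distinct score cutoff (classification positive iff
score ≥ cutoff) and the AUC is the trapezoidal integral of the (FPR, TPR)
path, which equals the probability that a random positive outscores a
random negative with ties counted half — the test suite asserts this
equivalence against a brute-force concordance oracle to 1e−9.

## Cutoffs and the pseudo-contour map

Each mapped model's cutoff is calibrated where sensitivity equals
specificity: the curves are evaluated on a 0.001-step cutoff grid and the
first sign change of (sensitivity − specificity) is linearly interpolated
(an exact grid-point zero is returned as-is). Boundary-inclusive
classification (≥ cutoff) makes cutoff 0 give sensitivity exactly 1. A
fixed 0.50 cutoff for all thresholds is available as a config option for
comparison maps.

Binary exceedance maps are combined into ordinal concentration bands by
the highest-exceeded-threshold rule: a cell whose 5 µg/L map is 1 but
whose 10 µg/L map is 0 falls in the 5–10 band, a cell exceeding nothing
falls below the lowest threshold. Because the five models are calibrated
independently, nothing forces their maps to nest; non-nested cells are
flagged in an inconsistency mask (typically a few percent of cells) and
still resolved by the same rule. The 1 µg/L model is excluded from
mapping by default: its discrimination sits at the assay's detection
limit and is barely better than chance.

## Exposure and health risk

Population is overlaid cellwise (density × cell area, conservation
asserted to rounding error). Cells are classed rural when density ≤ 400
persons/km² (configurable; any density-based split is a crude proxy for
administrative classification, which is why the threshold is exposed).
Exposed population = rural × 0.48 + urban × 0.29, the fractions of rural
and urban households relying on untreated groundwater sources.

Health burden uses the multistage dose–response forms with nonnegative
parameters q₁, q₂, k, m and Heaviside onset at age m:

  p(c,t) = 1 − exp(−(q₁c + q₂c²)(t−m)^k H(t−m))   (skin-cancer prevalence)
  h(c,t) = k(q₁c + q₂c²)(t−m)^(k−1) H(t−m)        (internal-cancer incidence)

linked by h = d/dt[−ln(1−p)], an identity the tests verify numerically on
a grid where 1−p is well away from the double-precision floor (for large
cumulative hazard, p rounds to 1 and the log-difference quotient is
meaningless — a numerical property, not a model one). At t = m with k < 1
the incidence diverges and is rejected; k ≥ 1 uses the continuous limit.
Aggregation sums exposed persons × rate over bands, rural/urban strata,
sexes and 5-year age bins evaluated at bin midpoints. Each band enters at
a representative concentration: band midpoints by default, with the
open-ended >10 band pegged at 15 µg/L — a deliberate, prominent
configuration point, since any within-band concentration distribution is
an assumption, not data. The shipped dose-response parameter values are
generic order-of-magnitude defaults in the multistage form (chosen so a
low-hazard region yields a small burden relative to its exposed
population); real assessments must substitute cohort-fitted potencies.

## Synthetic data: what it emulates and what it does not

The generator produces spatially autocorrelated continuous covariates
(white noise convolved with a disc kernel, re-standardized; radius 0
disables autocorrelation), 0/1 indicator layers from median-thresholded
smoothed fields, and wells whose exceedance of every threshold follows a
known sparse logistic model. One latent uniform per well is compared to
the per-threshold probabilities, which makes each indicator marginally
Bernoulli with the correct probability *and* nests the indicators across
thresholds; the emitted concentration is drawn uniformly within the band
between the highest exceeded threshold and the next (top band uniform on
10–30 µg/L, echoing the ~26 µg/L maxima typical of low-hazard surveys).
Threshold intercepts are calibrated by root-solving so grid-mean
exceedance probabilities match the survey-like fractions 24/398 … 301/398
at 10 … 1 µg/L. The population raster is a log-normal (smoothed, then
exponentiated) field normalized to a fixed total — 70,445,000 by default,
a state-scale anchor — on a default 64×64 grid of 7 km cells (≈ 200,000
km², so mean density ≈ 350 persons/km² and the rural/urban density split
is meaningful).

Passing recovery tests on these data shows the chain can find a sparse
logistic signal under realistic class imbalance and spatial smoothing. It
does **not** show robustness to what real surveys add: measurement error
and detection-limit censoring, preferential well placement, covariate
misregistration, non-logistic dose-location relationships, or strong
cross-covariate correlation structures beyond what smoothing induces.

## Problem sizes and numerics

The shipped test suite and acceptance script scale the study down to keep
runs fast while leaving the Monte-Carlo tolerances meaningful: screening
repeats and ensemble runs of 50–100 on 2000-well synthetic studies (20
replicate studies for recovery), 1000 simulations at n = 500 for the
Hosmer–Lemeshow calibration check, 32×32–64×64 grids. The statistical
engine is identical at full scale; `PipelineConfig` defaults keep the
1000-repeat / 1000-run design. Stepwise fits are cached per run by
variable combination; logistic fits use Newton's method (statsmodels)
with a BFGS fallback and a convergence flag that excludes separated fits
from ensemble tallies.

## Known limitations

- Exceedance models at different thresholds are fitted independently;
  the package reports but does not enforce cross-threshold coherence
  (no isotonic coupling of probability surfaces).
- The Hosmer–Lemeshow gate is applied to held-out data with the
  conventional g − 2 df reference; its null calibration is verified by
  simulation for the in-sample case only.
- Rural/urban classification by a density threshold is a proxy; exposure
  totals inherit its error.
- Dose-response parameter uncertainty is not propagated; outputs are
  point estimates, linear in exposed population.
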