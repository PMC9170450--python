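# Methods

## The model

The package predicts wetland ecosystem-service unit values by benefit
transfer: a meta-regression calibrated on a database of published valuation
cases. Each observation is one unit value V (yuan/(hm²·yr)) for one service
at one wetland, deflated to a common base year (default 2013) by the
consumer-price-index ratio index(base)/index(year). The regression is linear
on the log scale:

    ln V_ij = β0 + βw·X_wj + βc·(X_dj ⊙ X_cj) + βm·X_mi + U_ij

* **X_w** — natural covariates of the wetland (defaults in the generator:
  ln area, patch density, shape index).
* **X_d** — the spatial supply score, X_d = Σ_services N·A, where N is the
  wetland-type's 0–10 integer capacity for a service and A its area in hm².
  By default the sum runs over all services (X_d is the wetland's total
  supply capacity); a per-service variant is available via the design spec's
  `xd_services`.
* **X_d ⊙ X_c** — the supply score multiplies each environmental/
  socioeconomic covariate element-wise (defaults: ln GDP, ln population
  density, industry index). The interaction is implemented as a scalar times
  a vector; the product notation alone does not dictate a structure, and this
  is the simplest member of that family.
* **X_m** — one-hot indicators for the observation's service type and
  evaluation method. One reference category is dropped per group: keeping
  every 0/1 column alongside an intercept would be exactly collinear.
* **U** — i.i.d. errors on the ln scale.

Continuous covariates (X_w and the interaction columns) are z-scored on the
training sample. This is purely a conditioning device: stored means/scales
are replayed at prediction time, so predictions are invariant under affine
rescaling of any input covariate, and coefficients are reported on both the
standardized and the original scale (`CouplingModel.coefficients`).

Assumptions worth keeping in mind: one linear surface over all services and
methods (heterogeneity enters only through intercept shifts), errors
homoskedastic on the log scale, covariates measured without error, and cases
treated as independent (no within-study clustering or spatial
autocorrelation).

## Calibration, outliers, cross-validation, retransformation

* **OLS** with a hard failure on rank deficiency (the offending columns are
  named) and on designs without residual degrees of freedom.
* **Outlier rule**: one preliminary fit, removal of rows with internally
  studentized residual |r| > 2.5, one refit. The rule is a single pass by
  default — it names one cut, not an iteration — with an iterative mode
  behind a flag. Under clean normal errors the rule removes ≈ 1.2 % of rows
  (the |r| > 2.5 tail), which the acceptance checks verify empirically.
* **Leave-one-out CV** uses the exact algebraic identity
  e_(−i) = e_i/(1 − h_i) with h the hat-matrix diagonal; a literal n-refit
  implementation is kept as an oracle and the two agree to 1e−8 in tests.
  Reported: RMSE of LOO residuals on the ln scale, and the mean absolute
  transfer error on the value scale, |exp(ŷ_(−i)) − V_i|/V_i.
* **Retransformation**: exp(·) of a log-scale prediction is biased low;
  the default correction is Duan's smearing factor (mean of exp(residuals)),
  with naive exp and the normal-theory exp(σ²/2) selectable.

## AHP weighting

Service weights come from reciprocal pairwise-comparison matrices: one over
beneficiary levels (local, provincial, national, global) and one over
services per level. Priorities are the normalized principal right eigenvector
(power iteration, tolerance 1e−12, ≤ 10 000 iterations); consistency is
CI = (λ_max − n)/(n − 1), CR = CI/RI(n) with Saaty's random-index table, and
matrices with CR > 0.1 (configurable) are rejected by name. The comprehensive
weight of a service is Σ_levels levelweight × serviceweight, renormalized to
sum 1. A frozen ten-entry weight table from the coastal-wetland case study is
packaged (`published_weights`); its raw entries sum to 0.9991 from rounding and
are renormalized on use. Computed weights supersede the fixture whenever a
hierarchy is supplied.

## Supply matrix

Raw capacities are max-scaled to 0–10 integers, by service column by default
(capacity is relative within a service; a `global` axis is available),
rounding half-up. Re-normalizing an already normalized matrix reproduces it.
Published versions of this table print no numbers, so every matrix in this
repository is synthetic and generated by code.

## The synthetic-data generator

The generator emulates the structure of the calibration database — 62 cases
yielding 349 observations over 6 wetland types, 8 final services and 4
evaluation methods, observation years 1995–2013 deflated to 2013 — with
known ground truth. Stated distributional assumptions (the source database
is described only categorically):

| quantity | distribution | default |
|---|---|---|
| wetland area (hm²) | ln-normal | ln-mean 6.0, ln-sd 1.0 (median ≈ 400 hm²) |
| ln GDP, ln population density | normal | (10.0, 0.8), (5.5, 0.7) |
| patch density, shape index, industry index | normal | (5, 2), (1.5, 0.3), (0.5, 0.15) |
| CPI | multiplicative drift | +2.5 %/yr, noise sd 0.01 |
| ln-scale noise sd σ | — | 0.3 |
| coefficients β | uniform ±0.5, intercept 8.0 | drawn once per seed, recorded |
| AHP matrices | consistent × exp(N(0, τ²)) jitter | τ = 0.05 (CR ≪ 0.1) |
| observations per case | 1 + multinomial | — |
| outliers | fraction 0 by default; planted as ±shift·σ on ln V | shift 10σ when enabled |

Observed values are produced by the forward model itself: the generator
builds the same design matrix the calibration code builds, applies the true
coefficients, adds ln-normal noise, and de-deflates each value to its nominal
year through the inverse CPI ratio. Because generation and calibration share
one design construction, noise-free recovery is exact to machine precision —
a correctness check on the whole design path, not a statistical statement.

What the generator does **not** emulate: real geography or CPI history,
spatially correlated covariates, heteroskedastic or correlated errors,
publication selection in which services get valued, and systematic
method-specific biases beyond an intercept shift. Passing tests therefore
demonstrate that the estimators do what they claim under the stated model,
not that the model is adequate for any particular real database.

## Problem sizes and numerical choices

Simulation-based checks run at the database's own scale (n = 349, p = 17):
200 seeds for coefficient coverage and LOO RMSE, 100 seeds for outlier
operating characteristics, 100 random draws for the AHP and supply-score
oracles — sizes chosen so each check is a tight distributional statement
while the whole suite stays interactive. Ties in supply-matrix rounding go
up (half-up); the power iteration starts uniform; degenerate inputs fail
loudly (zero-variance covariates, all-zero supply rows/columns, missing CPI
years, covariates absent from a case — never imputed). All stochastic
routines take an explicit seed (package default 20130101).

## Known limitations

* The interaction structure (scalar X_d times each X_c) and the biomass
  adjustment of the equivalence table (a single multiplicative factor) are
  the simplest implementations consistent with their verbal definitions.
* Per-method value contrasts are exposed through the βm coefficients, but the
  package does not attempt to reproduce any particular published method
  ratio; the comparison design behind such ratios is underdetermined.
* Totals aggregate predicted unit values over inventory areas; the optional
  AHP-weighted composite is an index (weights sum to 1), not an alternative
  total.
* No spatial-autocorrelation adjustment, no Bayesian estimation, no GIS
  raster processing: inputs are tabular (CSV/JSON; GeoJSON attributes only).
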