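# Statistical methods

This note records the exact definitions and algorithms implemented in
`cvdrisk`, in pipeline order.

## 1. Synthetic population (`cvdrisk.synthetic`)

Patients are assigned to practices with log-normal size variation; each
practice carries a normal frailty on the log hazard (SD 0.10 by default).
Covariates are drawn from sex-specific marginals matched to primary-care
summary statistics; the generating risk equation is a known per-sex Cox model
(`default_true_coefficients`), so downstream estimates can be checked for
parameter recovery.

Event times use inverse-CDF sampling from the baseline family: with
`U ~ Uniform(0,1)` and cumulative baseline hazard `H₀`, the time solves
`H₀(T)·exp(η) = −ln U`. Weibull (`H₀(t) = (t/scale)^shape`) and Gompertz
families are supported. Censoring comes from registration/deregistration,
death from other causes, and the study end.

Missingness is applied per patient and variable kind (all-or-nothing removal
of a kind's observations). A shared per-patient "recording propensity" factor
correlates missingness across variables, reproducing the empirical pattern
that poorly recorded patients are missing several covariates at once.
Blood-pressure readings include within-person visit-to-visit noise so that a
five-year SD of repeated readings is a meaningful covariate.

## 2. Cohort assembly (`cvdrisk.cohort`)

Entry is the latest of: study start, 25th birthday, registration + 1 year,
practice data-quality date. Exit is the earliest of: outcome, death,
deregistration, study end; an outcome on the exit day counts as an event.
Sequential exclusions are tallied in an `ExclusionLedger` whose arithmetic is
validated (`included = identified − missing deprivation − prior CVD −
baseline statin`). Ages are restricted to [25, 85) at entry.

Outcomes are ascertained across GP, hospital and mortality sources, each
with its own code dialect (Read-style prefixes for GP, ICD-10 for
hospital/mortality, ICD-9 accepted on early mortality records). The first
qualifying record strictly after entry defines the event date and subtype
(MI, angina, TIA, ischaemic stroke). Baseline covariates take the latest
value before entry; cholesterol values recorded after a first statin
prescription are not used. The SBP variability covariate is the SD of
readings in the five years before entry (≥ 2 readings required).

## 3. Multiple imputation (`cvdrisk.impute`)

Chained equations with `m` completed datasets (default 5) and 10 cycles,
run separately by sex. Continuous variables use predictive-mean matching
(k = 5 donors) on an approximate Bayesian linear model: coefficients are
drawn as `β* = β̂ + σ* L⁻ᵀ z` using a Cholesky factor `L` of X′X (with an
escalating ridge for near-singular designs) and `σ*` from the scaled
inverse-χ² posterior. Skewed variables (BMI, SBP variability, total and HDL
cholesterol) are imputed on the log scale. Smoking status uses a bootstrap
multinomial logistic model. The Nelson–Aalen cumulative hazard and the event
indicator enter every imputation model as auxiliaries; the deprivation score
is never imputed (cohorts exclude patients missing it). The cholesterol
ratio is recomputed from its imputed components.

Rubin's rules pool any scalar across imputations: point estimate `Q̄`,
total variance `T = W̄ + (1 + 1/m)·B`, with Barnard–Rubin small-sample
degrees of freedom for intervals. Coefficient vectors pool the same way with
matrix within/between components.

## 4. Cox fitting and fractional polynomials (`cvdrisk.coxfp`)

The partial likelihood supports Breslow (default) and Efron tie handling,
maximised by Newton–Raphson with step-halving. Design columns are scaled to
unit SD internally (estimates and covariance are mapped back), making the
monotone-likelihood guard scale-free; constant or collinear columns raise
errors rather than returning garbage.

Fractional polynomials consider powers {−2, −1, −0.5, 0, 0.5, 1, 2, 3}
(0 = log; repeated powers add an `x^p ln x` term). The best FP2 is compared
by the Royston–Altman closed test: against the null (4 df), against linear
(3 df), against the best FP1 (2 df), each at α = 0.05. Non-positive
variables are shifted to a positive origin before transformation. FP powers
are selected once on complete cases and frozen across imputations.

New candidate binary predictors are retained only if the pooled hazard ratio
lies outside 0.90–1.10 **and** p < 0.01; established predictors bypass the
rule. Age interactions, when enabled, are screened by Wald tests at α = 0.01.

The baseline survivor function is the Breslow estimator evaluated at whole
years for a reference subject (continuous terms at their centring values,
binaries at zero); it is a right-continuous step function.

## 5. Risk engine (`cvdrisk.engine`)

A `CoefficientSet` (JSON-serialisable) lists `TermSpec`s — linear, FP,
binary, dummy-coded categorical, and interaction terms — with centring
values and a baseline survivor table. Scoring computes
`risk = 1 − S₀(t)^exp(η)`, validates required covariates, optionally clamps
continuous inputs to plausible ranges, and classifies against a threshold
(≥ threshold ⇒ high; the boundary is inclusive).

## 6. Validation (`cvdrisk.validate`)

- **Harrell's C**: comparable pairs under censoring, ties in predicted risk
  counted one-half, optional truncation at the forecast horizon. The fast
  implementation sorts by time and counts order statistics with a Fenwick
  tree (O(n log n)); it is verified against a brute-force O(n²) oracle.
  Standard errors use a delete-group jackknife; practice-level C uses a
  leave-one-practice-out jackknife.
- **D statistic**: the prognostic index is replaced by Blom rankits scaled
  by κ = √(8/π) and refitted in a Cox model; the coefficient is D. R²_D =
  (D²/κ²) / (π²/6 + D²/κ²).
- **Calibration**: tenths of mean predicted risk against Kaplan–Meier
  observed risk at the horizon, with Greenwood log(−log) confidence limits.
- **Meta-analysis**: DerSimonian–Laird random effects over practice-level C
  statistics; I², τ², and a t-based prediction interval for a new practice.
- **Reclassification**: a 2×2 table at the treatment threshold between two
  models, with Kaplan–Meier observed risk inside each reclassified cell.

Performance metrics computed per imputation are pooled with Rubin's rules;
predicted risks are averaged across imputations before calibration and
reclassification.

## 7. Pipeline (`cvdrisk.pipeline`)

Practices are split into derivation/validation sets by seeded simple random
sampling (default 75/25). Models are derived per sex: model A uses the
established predictor set with severe kidney disease only; model B widens
the kidney definition and adds the new candidates that pass the retention
rule; model C adds SBP variability. Validation computes pooled C/D/R²_D,
calibration, a practice-level meta-analysis, and reclassification between
consecutive models. Bundles are written with a config hash and manifest so
any run is reproducible from its own output.
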