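# cvdrisk

Derivation, validation and deployment of QRISK3-style 10-year cardiovascular
disease (CVD) risk equations from longitudinal primary-care records — with a
synthetic electronic-health-record (EHR) generator so the entire workflow can
be exercised end to end without access to real patient data.

## The scientific problem

Primary-care risk equations of the form

```
risk(t) = 1 − S₀(t)^exp(η)
```

predict a patient's probability of a first cardiovascular event within *t*
years. `η` is a linear predictor from a sex-specific Cox proportional-hazards
model; `S₀(t)` is the baseline survivor function for a reference subject.
Deriving such an equation from raw EHR tables is most of the work:

- **Cohort assembly** — entry/exit dates from registration and study windows,
  sequential exclusions (missing deprivation score, prior CVD, baseline
  statin use), outcome ascertainment across three linked sources (GP records,
  hospital admissions, mortality registers) with different code dialects,
  and baseline covariate extraction with realistic missingness.
- **Multiple imputation** — chained equations (MICE) with predictive-mean
  matching, the Nelson–Aalen cumulative hazard and the event indicator as
  auxiliaries, run separately by sex.
- **Model fitting** — Cox models with fractional-polynomial (FP) transforms
  for continuous covariates chosen by a deviance-based closed test, a
  retention rule for new candidate predictors (hazard ratio outside
  0.90–1.10 and p < 0.01), optional age interactions, and Rubin's rules to
  pool coefficients across imputations.
- **Validation** — Harrell's C (with an O(n log n) implementation verified
  against an O(n²) oracle), the Royston–Sauerbrei D statistic and R²_D,
  calibration by tenths of predicted risk against Kaplan–Meier observed
  risk, a random-effects meta-analysis of practice-level C statistics, and
  risk reclassification across the 10% treatment threshold between nested
  model variants (A/B/C).

The package implements each stage as an importable module plus a `cvdrisk`
command-line interface, and ships a population simulator whose generating
model is a known Cox equation — so the full pipeline can be tested for
parameter recovery, calibration self-consistency, and discrimination.

## Worked example: scoring a patient

```python
from cvdrisk import default_true_coefficients, predict_risk

coeffs = default_true_coefficients("F")  # a bundled example coefficient set
profile = {
    "age": 58, "townsend": 1.2, "sbp": 134, "sbp_sd": 9.5, "bmi": 28.0,
    "chol_ratio": 4.6, "smoking": "light", "ethnicity": "white_or_missing",
    "type2_diabetes": 0, "treated_hypertension": 1, "fh_chd": 0,
    "type1_diabetes": 0, "atrial_fibrillation": 0, "rheumatoid_arthritis": 0,
    "ckd345": 0, "migraine": 1, "sle": 0, "severe_mental_illness": 0,
    "corticosteroid": 0, "atypical_antipsychotic": 0,
}
res = predict_risk(coeffs, profile, t=10, threshold=0.10)
print(f"10-year CVD risk: {100 * res.risk:.1f}%")
print(f"linear predictor: {res.linear_predictor:.3f}")
print(f"classification at the 10% threshold: {res.classification}")
```

Output (verbatim):

```
10-year CVD risk: 33.4%
linear predictor: 3.008
classification at the 10% threshold: high
```

Any fitted or published coefficient set saved in the package's JSON schema
can be loaded with `CoefficientSet.from_json` and scored the same way; the
engine validates required covariates and refuses profiles with missing ones.

## Worked example: the full pipeline

```bash
# one command: simulate -> split by practice -> build cohorts -> impute ->
# fit models A/B/C by sex -> validate, writing a reproducible bundle
cvdrisk run-all --n-patients 30000 --seed 1 --out results/run1

# or stage by stage
cvdrisk simulate --n-patients 30000 --seed 1 --out data/
cvdrisk build-cohort --tables data/ --out cohort.csv
cvdrisk impute --cohort cohort.csv -m 5 --seed 17 --out imputed/
cvdrisk fit --imputed imputed/ --cohort cohort.csv --models A,B,C --out fits/
cvdrisk score --coefficients fits/coefficients_B_F.json --covariates patient.json
cvdrisk validate --coefficients fits/coefficients_B_F.json --cohort cohort.csv --out report.json
```

Every output bundle carries a SHA-256 config hash and a manifest sufficient
to reproduce it.

On a 30 000-patient synthetic population (seed 1) the pooled validation
metrics land in the expected range for this class of model — Harrell's C
about 0.83–0.84, D about 2.1–2.3, and R²_D about 51–57% depending on sex —
with mean absolute calibration gaps under 2 percentage points per tenth.

## Reproduction

```bash
# full test suite (unit + acceptance), ~1 minute on one CPU
python -m pytest -q

# acceptance evidence: closed-form checks on the bundled published summary
# numbers plus a seeded end-to-end synthetic run (~1 minute)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` writes every headline quantity as
`{"name": {"value": ..., "n": ...}}`: `published_*` entries are deterministic
arithmetic on bundled summary counts (for example
`published_derivation_included` = 7,889,803); `synthetic_*` entries come from
the seeded pipeline run and vary with `--seed`.

## Package layout

| Module | Contents |
| --- | --- |
| `cvdrisk.synthetic` | population simulator, event-time inverse-CDF sampling, missingness |
| `cvdrisk.cohort` | entry/exit dates, exclusion ledger, outcome ascertainment, incidence |
| `cvdrisk.impute` | MICE with PMM and bootstrap multinomial models, Rubin's rules |
| `cvdrisk.coxfp` | Cox partial likelihood (Breslow/Efron), FP selection, pooled fits |
| `cvdrisk.engine` | coefficient schema, linear predictor, risk scoring |
| `cvdrisk.validate` | Harrell's C, D/R²_D, calibration, meta-analysis, reclassification |
| `cvdrisk.pipeline` | practice split, model derivation/validation orchestration |
| `cvdrisk.cli` | `cvdrisk` command-line interface |
| `cvdrisk.published` | bundled published summary numbers used by acceptance checks |
| `cvdrisk.compat` | harness for externally published coefficient files |

See `docs/methods.md` for the statistical methods in detail.
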