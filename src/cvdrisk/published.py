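"""Published summary numbers for the cardiovascular risk-score study.

These are the publicly reported headline counts and statistics of the
QRISK3 derivation/validation study: exclusion-ledger counts,
validation D statistics, reclassification counts, event-source shares and
statin-exposure person-years.  They serve as *inputs* to arithmetic
cross-checks (ledger conservation, D -> R2_D, printed proportions); the
underlying patient data is proprietary and is not reproduced here.
"""

from __future__ import annotations

# sequential exclusion counts (identified, no deprivation score, prior CVD,
# baseline statin) for the derivation and validation cohorts
DERIVATION_LEDGER = {
    "identified": 8_602_833,
    "missing_townsend": 31_433,
    "prior_cvd": 344_669,
    "baseline_statin": 336_928,
}
VALIDATION_LEDGER = {
    "identified": 2_918_082,
    "missing_townsend": 13_862,
    "prior_cvd": 118_057,
    "baseline_statin": 114_865,
}

#: validation D statistic, model B (women, men)
D_STATISTIC_MODEL_B = {"F": 2.48, "M": 2.26}

#: printed numerator/denominator pairs for headline proportions
PROPORTIONS = {
    # 10-year risk >= 10% under model A, of the validation cohort
    "high_risk_model_a": (458_263, 2_671_298),
    # risk >= 20% under model A
    "risk_ge_20pct_model_a": (214_451, 2_671_298),
    # model-A high-risk patients reclassified low by model B
    "reclassified_down_a_to_b": (10_948, 458_263),
    # statin-free person-years of derivation follow-up
    "statin_free_person_years": (46_940_777, 50_764_868),
    # myocardial infarction share of incident events (derivation)
    "mi_share_of_events": (78_327, 363_565),
    # events recorded only on the GP record
    "gp_only_share_of_events": (92_936, 363_565),
    # statin initiation after entry, before an event or censoring
    "post_baseline_statin": (696_387, 7_889_803),
}

#: practice split: 1309 practices, three quarters to derivation
PRACTICE_SPLIT = {"total": 1309, "derivation": 981, "validation": 328}

#: derivation incidence (Table 2 totals): cases and person-years by sex
INCIDENCE_TOTALS = {
    "F": {"cases": 160_549, "person_years": 25_943_236},
    "M": {"cases": 203_016, "person_years": 24_821_632},
}

#: clinical example covariate profiles (Table 6) and printed 10-year risks (%)
CLINICAL_EXAMPLES = [
    {
        "example": 1, "sex": "M", "age": 44, "bmi": 27.2, "chol_ratio": 6.1,
        "sbp": 130, "sbp_sd": 6.0, "ethnicity": "white_or_not_recorded",
        "smoking": "heavy", "migraine": 1,
        "printed_risk_pct": {"A": 9.2, "B": 11.0, "C": 11.0},
    },
    {
        "example": 2, "sex": "M", "age": 45, "bmi": 22.4, "chol_ratio": 6.3,
        "sbp": 115, "sbp_sd": 40.0, "ethnicity": "white_or_not_recorded",
        "smoking": "non", "type2_diabetes": 1, "erectile_dysfunction": 1,
        "printed_risk_pct": {"A": 8.3, "B": 9.9, "C": 13.0},
    },
    {
        "example": 3, "sex": "M", "age": 48, "bmi": 29.7, "chol_ratio": 5.0,
        "sbp": 124, "sbp_sd": 3.1, "ethnicity": "white_or_not_recorded",
        "smoking": "light", "migraine": 1, "corticosteroid": 1,
        "printed_risk_pct": {"A": 6.4, "B": 11.0, "C": 11.0},
    },
    {
        "example": 4, "sex": "F", "age": 55, "bmi": 24.9, "chol_ratio": 3.2,
        "sbp": 130, "sbp_sd": 22.0, "ethnicity": "white_or_not_recorded",
        "smoking": "moderate", "fh_chd": 1,
        "printed_risk_pct": {"A": 11.0, "B": 10.0, "C": 11.0},
    },
    {
        "example": 5, "sex": "F", "age": 61, "bmi": 33.7, "chol_ratio": 4.8,
        "sbp": 155, "sbp_sd": 33.0, "ethnicity": "black_african",
        "smoking": "former", "atypical_antipsychotic": 1, "severe_mental_illness": 1,
        "printed_risk_pct": {"A": 9.4, "B": 13.0, "C": 15.0},
    },
    {
        "example": 6, "sex": "M", "age": 48, "bmi": 30.0, "chol_ratio": 4.2,
        "sbp": 140, "sbp_sd": 0.0, "ethnicity": "white_or_not_recorded",
        "smoking": "non", "treated_hypertension": 1, "migraine": 1,
        "printed_risk_pct": {"A": 9.2, "B": 11.0, "C": 9.5},
    },
]
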