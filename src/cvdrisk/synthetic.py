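"""Synthetic longitudinal primary-care tables with a known hazard structure.

The generator emulates the structure of a linked UK primary-care research
extract: staggered cohort entry over 1998-2015 driven by registration and
practice-installation dates, practice clustering (a lognormal frailty on the
hazard), repeated blood-pressure/BMI/cholesterol/smoking records before
baseline, diagnoses split across GP (Read-style codes), hospital (ICD-10)
and mortality (ICD-10, ICD-9 in 1998-2000) sources, prescriptions, and
per-variable recording rates matching a configurable target (defaults follow
the published baseline table of the cohort the models were derived on).

Event times are drawn from a known Cox model by inversion,
``T = H0^{-1}(-log U / exp(eta))``, so every downstream stage (cohort
assembly, imputation, fitting, validation) can be checked against truth.

Recording of the four baseline measurements is correlated within patients
through a shared Gaussian propensity factor; the loading 0.3725 reproduces
the published complete-data fractions (28.5% women / 24.6% men) while each
marginal recording rate stays at its configured value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DAYS_PER_YEAR, _entry_dates
from .model import CoefficientSet, TermSpec, build_design_matrix

#: shared recording-propensity loading (see module docstring)
RECORDING_COMMON_FACTOR = 0.3725

ETHNICITIES = (
    "white_or_not_recorded",
    "indian",
    "pakistani",
    "bangladeshi",
    "other_asian",
    "black_caribbean",
    "black_african",
    "chinese",
    "other",
)
ETHNICITY_PROBS = (0.887, 0.019, 0.010, 0.008, 0.013, 0.009, 0.019, 0.008, 0.027)

SMOKING_LEVELS = ("non", "former", "light", "moderate", "heavy")
# recorded-category shares (women, men)
SMOKING_PROBS = {
    "F": (0.600, 0.172, 0.127, 0.066, 0.035),
    "M": (0.487, 0.198, 0.169, 0.084, 0.062),
}

#: baseline condition/exposure prevalences by sex (women, men)
FLAG_PREVALENCE = {
    "fh_chd": (0.120, 0.093),
    "type1_diabetes": (0.003, 0.003),
    "type2_diabetes": (0.012, 0.015),
    "treated_hypertension": (0.056, 0.042),
    "rheumatoid_arthritis": (0.011, 0.005),
    "atrial_fibrillation": (0.004, 0.005),
    "ckd345": (0.005, 0.003),
    "ckd45": (0.002, 0.002),
    "migraine": (0.064, 0.027),
    "corticosteroid": (0.024, 0.015),
    "sle": (0.0010, 0.0001),
    "atypical_antipsychotic": (0.005, 0.005),
    "severe_mental_illness": (0.068, 0.043),
    "hiv_aids": (0.001, 0.002),
    "erectile_dysfunction": (0.0, 0.023),
}

#: default per-variable missingness (probability a measurement is unrecorded)
DEFAULT_MISSINGNESS = {
    "bmi": {"F": 0.272, "M": 0.360},
    "cholesterol": {"F": 0.602, "M": 0.621},
    "sbp": {"F": 0.172, "M": 0.317},
    "smoking": {"F": 0.150, "M": 0.223},
    "townsend": {"F": 0.004, "M": 0.004},
}

OUTCOME_SUBTYPE_PROBS = {"MI": 0.215, "angina": 0.418, "TIA": 0.136, "ischaemic stroke": 0.231}
SUBTYPE_CODES = {
    "read": {"MI": "G30", "angina": "G33", "TIA": "G65", "ischaemic stroke": "G64"},
    "icd10": {"MI": "I21", "angina": "I20", "TIA": "G45", "ischaemic stroke": "I63"},
    "icd9": {"MI": "410", "angina": "413", "TIA": "435", "ischaemic stroke": "434"},
}
CONDITION_CODES = {
    "fh_chd": "12C2",
    "type1_diabetes": "C10E",
    "type2_diabetes": "C10F",
    "hypertension_dx": "G20",
    "rheumatoid_arthritis": "N040",
    "ckd3": "K053",
    "ckd4": "K054",
    "ckd5": "K055",
    "atrial_fibrillation": "G573",
    "migraine": "F26",
    "sle": "N000",
    "severe_mental_illness": "E10",
    "hiv_aids": "A788",
    "ed_diagnosis": "ED01",
}


def default_true_coefficients(sex: str) -> CoefficientSet:
    """The generating ('true') risk equation for one sex.

    Log-hazard ratios echo the magnitudes reported for this class of model:
    smoking grades up to ~2.3, diabetes 2.4-5.7, age dominating.  BMI enters
    on the log scale (a curved effect for the FP machinery to find); all
    other continuous terms are linear.  Continuous terms are centred at the
    population means so the baseline Weibull refers to a 45-year-old
    reference subject.
    """
    w = sex == "F"
    ln = np.log
    terms: list[tuple[TermSpec, float]] = [
        (TermSpec("age", "linear", center=45.0), 0.095 if w else 0.085),
        (TermSpec("townsend", "linear", center=0.45), ln(1.47 if w else 1.18) / 5),
        (TermSpec("sbp", "linear", center=123.2 if w else 129.2), ln(1.15 if w else 1.14) / 20),
        (TermSpec("sbp_sd", "linear", center=9.3 if w else 9.9), ln(1.08 if w else 1.11) / 10),
        (TermSpec("chol_ratio", "linear", center=3.7 if w else 4.4), ln(1.17 if w else 1.19)),
        (TermSpec("bmi", "fp", power=0.0, center=float(ln(25.4 if w else 25.9))), 0.9),
    ]
    smoking_hr = {"F": (1.15, 1.76, 1.95, 2.34), "M": (1.21, 1.74, 1.90, 2.21)}[sex]
    for lev, hr in zip(SMOKING_LEVELS[1:], smoking_hr):
        terms.append((TermSpec("smoking", "dummy", level=lev), ln(hr)))
    eth_hr = {
        "F": (1.32, 1.76, 1.35, 1.08, 0.84, 0.68, 0.73, 0.84),
        "M": (1.32, 1.61, 1.70, 1.04, 0.70, 0.67, 0.66, 0.77),
    }[sex]
    for lev, hr in zip(ETHNICITIES[1:], eth_hr):
        terms.append((TermSpec("ethnicity", "dummy", level=lev), ln(hr)))
    flag_hr = {
        "fh_chd": (1.58, 1.72),
        "type1_diabetes": (5.66, 3.47),
        "type2_diabetes": (2.92, 2.37),
        "treated_hypertension": (1.71, 1.73),
        "rheumatoid_arthritis": (1.24, 1.24),
        "atrial_fibrillation": (4.94, 2.44),
        "ckd345": (1.94, 2.09),
        "migraine": (1.36, 1.29),
        "corticosteroid": (1.82, 1.58),
        "sle": (2.15, 1.55),
        "atypical_antipsychotic": (1.29, 1.15),
        "severe_mental_illness": (1.14, 1.13),
    }
    for flag, (hr_f, hr_m) in flag_hr.items():
        terms.append((TermSpec(flag, "binary"), ln(hr_f if w else hr_m)))
    if not w:
        terms.append((TermSpec("erectile_dysfunction", "binary"), ln(1.25)))
    shape, scale = 1.2, 260.0
    s0 = {t: float(np.exp(-((t / scale) ** shape))) for t in range(1, 16)}
    return CoefficientSet(
        model_id="truth",
        sex=sex,
        terms=[t for t, _ in terms],
        coefficients=[b for _, b in terms],
        baseline_survival=s0,
        metadata={"baseline": {"family": "weibull", "shape": shape, "scale": scale}},
    )


@dataclass
class SimulationConfig:
    n_patients: int = 10_000
    n_practices: int = 20
    study_start: str = "1998-01-01"
    study_end: str = "2015-12-31"
    baseline_family: str = "weibull"  # or 'gompertz'
    baseline_shape: float = 1.2
    baseline_scale: float = 260.0
    frailty_sd: float = 0.10  # practice-level SD on the log hazard
    missingness_rates: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MISSINGNESS.items()})
    sbp_readings_mean: float = 4.0  # mean readings per patient in the 5y window
    sbp_within_sd_mean: dict = field(default_factory=lambda: {"F": 9.3, "M": 9.9})
    age_missingness_slope: float = 0.0  # MAR-given-age logit slope
    prior_cvd_rate: float = 0.040
    baseline_statin_rate: float = 0.039
    post_statin_rate: float = 0.088
    gp_only_outcome_share: float = 0.256
    true_coefficients: dict | None = None  # sex -> CoefficientSet
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_practices < 1:
            raise ValueError("n_practices must be >= 1")
        if self.baseline_family not in ("weibull", "gompertz"):
            raise ValueError("baseline_family must be 'weibull' or 'gompertz'")
        if pd.Timestamp(self.study_start) >= pd.Timestamp(self.study_end):
            raise ValueError("study_start must precede study_end")
        for var, by_sex in self.missingness_rates.items():
            for sex, r in (by_sex.items() if isinstance(by_sex, dict) else [("*", by_sex)]):
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"missingness rate for {var}/{sex} outside [0, 1]")
        for r in (self.prior_cvd_rate, self.baseline_statin_rate, self.post_statin_rate,
                  self.gp_only_outcome_share):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rate outside [0, 1]")

    def truth(self, sex: str) -> CoefficientSet:
        if self.true_coefficients and sex in self.true_coefficients:
            return self.true_coefficients[sex]
        return default_true_coefficients(sex)

    def manifest(self) -> dict:
        d = asdict(self)
        if self.true_coefficients:
            d["true_coefficients"] = {s: cs.to_dict() for s, cs in self.true_coefficients.items()}
        return d


# ---------------------------------------------------------------------------
# Event-time simulation
# ---------------------------------------------------------------------------

def simulate_event_times(
    eta,
    censor_times,
    baseline_family: str = "weibull",
    shape: float = 1.2,
    scale: float = 260.0,
    seed: int | np.random.Generator = 0,
):
    """Inverse-CDF draw of event times under a Cox model.

    T solves H0(T) = -log(U) / exp(eta).  Weibull: H0(t) = (t/scale)^shape.
    Gompertz: H0(t) = (scale/shape) (exp(shape t) - 1).  Returns
    (time, event) with time = min(T, censor) in years.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        bad = np.flatnonzero(~np.isfinite(eta))
        raise ValueError(f"non-finite linear predictor at rows {bad[:5].tolist()}")
    censor = np.asarray(censor_times, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(len(eta))
    target = -np.log(u) * np.exp(-eta)
    if baseline_family == "weibull":
        T = scale * np.power(target, 1.0 / shape)
    elif baseline_family == "gompertz":
        T = np.log1p(shape * target / scale) / shape
    else:
        raise ValueError(f"unknown baseline family {baseline_family!r}")
    event = T <= censor
    time = np.minimum(T, censor)
    return time, event


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def _recording_mask(
    patients: pd.DataFrame, rates: dict, var: str, rng: np.random.Generator,
    z_common: np.ndarray, age: np.ndarray, slope: float,
) -> np.ndarray:
    """True where the variable is RECORDED for the patient (correlated MAR)."""
    by_sex = rates.get(var)
    if by_sex is None:
        return np.ones(len(patients), dtype=bool)
    if not isinstance(by_sex, dict):
        by_sex = {"F": by_sex, "M": by_sex}
    r = np.where(patients["sex"].to_numpy() == "F",
                 by_sex.get("F", 0.0), by_sex.get("M", 0.0))
    if slope:  # shift the threshold with standardised age, keeping MAR
        age_std = (age - 45.0) / 15.0
        r = stats.norm.cdf(stats.norm.ppf(np.clip(r, 1e-12, 1 - 1e-12)) + slope * age_std)
    lam = RECORDING_COMMON_FACTOR
    eps = rng.standard_normal(len(patients))
    w = np.sqrt(lam) * z_common + np.sqrt(1.0 - lam) * eps
    # missing iff the propensity falls below the rate quantile
    return w > stats.norm.ppf(np.clip(r, 0.0, 1.0))


def apply_missingness(tables: dict, missingness_rates: dict, seed: int = 0,
                      age_slope: float = 0.0) -> dict:
    """Remove baseline measurements per patient with the configured rates.

    Removal indicators depend only on sex (and optionally age) -- missing at
    random by construction.  The 'cholesterol' rate removes total and HDL
    cholesterol jointly; 'townsend' blanks the deprivation score.  Original
    tables are left untouched (copies are returned).
    """
    rng = np.random.default_rng(seed)
    patients = tables["patients"].reset_index(drop=True)
    obs = tables["observations"].copy()
    out = {k: v.copy() for k, v in tables.items()}
    ref = pd.Timestamp("2005-01-01")
    age = (ref - pd.to_datetime(patients["date_of_birth"])).dt.days / DAYS_PER_YEAR
    z_common = rng.standard_normal(len(patients))

    kind_map = {
        "bmi": ("bmi",),
        "sbp": ("sbp",),
        "smoking": ("smoking_status",),
        "cholesterol": ("total_cholesterol", "hdl_cholesterol"),
    }
    drop_kinds_by_pid = {}
    for var, kinds in kind_map.items():
        recorded = _recording_mask(patients, missingness_rates, var, rng,
                                   z_common.to_numpy() if hasattr(z_common, "to_numpy") else z_common,
                                   age.to_numpy(), age_slope)
        missing_ids = set(patients.loc[~recorded, "patient_id"])
        for k in kinds:
            drop_kinds_by_pid[k] = missing_ids
    keep = np.ones(len(obs), dtype=bool)
    for k, ids in drop_kinds_by_pid.items():
        if ids:
            keep &= ~((obs["kind"] == k) & obs["patient_id"].isin(ids)).to_numpy()
    out["observations"] = obs[keep].reset_index(drop=True)

    if "townsend" in missingness_rates:
        recorded = _recording_mask(patients, missingness_rates, "townsend", rng,
                                   z_common, age.to_numpy(), 0.0)
        pat = out["patients"].copy()
        blank = pat["patient_id"].isin(set(patients.loc[~recorded, "patient_id"]))
        pat.loc[blank, "townsend"] = np.nan
        out["patients"] = pat
    return out


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _spaced_dates(entry_days: np.ndarray, counts: np.ndarray, window_days: float,
                  rng: np.random.Generator):
    """Uniform observation dates in [entry - window, entry) per patient."""
    rep_entry = np.repeat(entry_days, counts)
    offsets = rng.random(counts.sum()) * window_days
    return rep_entry - offsets


def generate_population(config: SimulationConfig) -> dict:
    """Generate the four linked tables; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)

    practice_ids = np.arange(config.n_practices)
    install = start - pd.to_timedelta(rng.integers(365, 9 * 365, config.n_practices), "D")
    upload_early = rng.random(config.n_practices) < 0.10
    upload = np.where(
        upload_early,
        start + pd.to_timedelta(rng.integers(8 * 365, 17 * 365, config.n_practices), "D"),
        np.datetime64(end),
    )
    frailty = rng.normal(0.0, config.frailty_sd, config.n_practices)

    practice = rng.integers(0, config.n_practices, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    is_f = sex == "F"
    age_2005 = rng.uniform(22.0, 90.0, n)
    dob = pd.Timestamp("2005-01-01") - pd.to_timedelta((age_2005 * DAYS_PER_YEAR).astype(int), "D")
    registration = start - pd.to_timedelta(rng.integers(-15 * 365, 10 * 365, n), "D")
    # registration cannot precede birth
    registration = pd.Series(registration).combine(pd.Series(dob), max).to_numpy()
    dereg = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")
    has_dereg = rng.random(n) < 0.20
    dereg[has_dereg] = (
        pd.Series(registration[has_dereg])
        + pd.to_timedelta((rng.exponential(12.0, has_dereg.sum()) * DAYS_PER_YEAR).astype(int) + 400, "D")
    ).to_numpy()
    ethnicity = rng.choice(ETHNICITIES, n, p=np.asarray(ETHNICITY_PROBS) / sum(ETHNICITY_PROBS))
    townsend = rng.normal(0.45, 3.25, n)

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "practice_id": practice,
            "date_of_birth": dob,
            "sex": sex,
            "ethnicity": ethnicity,
            "townsend": townsend,
            "registration_date": registration,
            "deregistration_date": dereg,
            "death_date": pd.NaT,
            "practice_install_date": pd.to_datetime(install[practice]),
            "last_upload_date": pd.to_datetime(upload[practice]),
        }
    )

    entry = _entry_dates(patients.set_index("patient_id"), start).reset_index(drop=True)
    entry_days = entry.astype("int64") // 86_400_000_000_000  # days since epoch
    age_entry = (entry - pd.to_datetime(patients["date_of_birth"])).dt.days / DAYS_PER_YEAR

    # ---- latent covariates ------------------------------------------------
    sbp_mean = np.where(is_f, rng.normal(123.2, 16.0, n), rng.normal(129.2, 14.0, n))
    sbp_mean = np.clip(sbp_mean, 80.0, 220.0)
    within_mu = np.where(is_f, config.sbp_within_sd_mean["F"], config.sbp_within_sd_mean["M"])
    sbp_within = np.clip(rng.lognormal(np.log(within_mu) - 0.18, 0.6, n), 1.0, 40.0)
    bmi = np.clip(np.where(is_f, rng.normal(25.4, 5.1, n), rng.normal(25.9, 4.2, n)), 15.0, 55.0)
    hdl = np.clip(np.where(is_f, rng.normal(1.6, 0.35, n), rng.normal(1.3, 0.30, n)), 0.6, 3.5)
    ratio = np.clip(np.where(is_f, rng.normal(3.7, 1.2, n), rng.normal(4.4, 1.4, n)), 1.5, 11.0)
    tchol = ratio * hdl
    smoking = np.empty(n, dtype=object)
    for s in ("F", "M"):
        m = sex == s
        smoking[m] = rng.choice(SMOKING_LEVELS, m.sum(), p=SMOKING_PROBS[s])

    flags = {}
    for flag, (pf, pm) in FLAG_PREVALENCE.items():
        p = np.where(is_f, pf, pm)
        flags[flag] = rng.random(n) < p
    # nested kidney-disease stages: stage 4/5 is a subset of stage 3-5
    flags["ckd345"] = flags["ckd345"] | flags["ckd45"]
    ckd45 = flags["ckd45"]
    ckd3_only = flags["ckd345"] & ~ckd45
    split45 = rng.random(n) < 0.5

    frame = pd.DataFrame(
        {
            "age": age_entry,
            "townsend": townsend,
            "sbp": sbp_mean,
            "sbp_sd": sbp_within,
            "bmi": bmi,
            "chol_ratio": ratio,
            "smoking": smoking,
            "ethnicity": ethnicity,
            **{k: v.astype(float) for k, v in flags.items()},
        }
    )

    eta = np.zeros(n)
    for s in ("F", "M"):
        m = sex == s
        truth = config.truth(s)
        X = build_design_matrix(frame[m], truth.terms)
        eta[m] = X @ np.asarray(truth.coefficients)
    eta += frailty[practice]

    # ---- censoring and events --------------------------------------------
    # non-CVD death, hazard rising with age
    death_rate = 0.002 * np.exp(0.085 * (age_entry - 45.0))
    t_death = rng.exponential(1.0 / np.clip(death_rate, 1e-6, None))
    admin = pd.concat(
        [
            pd.Series(pd.to_datetime(patients["deregistration_date"])),
            pd.Series(pd.to_datetime(patients["last_upload_date"])),
            pd.Series(end, index=patients.index),
        ],
        axis=1,
    ).min(axis=1)
    censor_years = np.minimum(
        (admin - entry).dt.days.to_numpy() / DAYS_PER_YEAR, t_death
    )
    censor_years = np.clip(censor_years, 0.0, None)
    time, event = simulate_event_times(
        eta, censor_years, config.baseline_family, config.baseline_shape,
        config.baseline_scale, rng,
    )
    death_by_other = (~event) & (t_death <= censor_years + 1e-12) & (t_death < (admin - entry).dt.days.to_numpy() / DAYS_PER_YEAR)
    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")
    death_date[death_by_other] = (
        entry[death_by_other] + pd.to_timedelta((t_death[death_by_other] * DAYS_PER_YEAR).astype(int), "D")
    ).to_numpy()
    patients["death_date"] = death_date

    outcome_date = pd.Series(pd.NaT, index=patients.index, dtype="datetime64[ns]")
    outcome_date[event] = entry[event] + pd.to_timedelta(
        np.maximum((time[event] * DAYS_PER_YEAR).astype(int), 1), "D"
    )
    subtype = rng.choice(
        list(OUTCOME_SUBTYPE_PROBS), n, p=list(OUTCOME_SUBTYPE_PROBS.values())
    )
    # fatal events also set the death date
    fatal = event & (rng.random(n) < 0.05)
    patients.loc[fatal, "death_date"] = outcome_date[fatal]

    # ---- observations -----------------------------------------------------
    obs_parts = []
    five_y = 5 * DAYS_PER_YEAR

    n_sbp = 2 + rng.poisson(max(config.sbp_readings_mean - 2.0, 0.0), n)
    rep = np.repeat(np.arange(n), n_sbp)
    dates = _spaced_dates(entry_days.to_numpy(), n_sbp, five_y - 1, rng)
    values = rng.normal(sbp_mean[rep], sbp_within[rep])
    obs_parts.append(pd.DataFrame({"patient_id": rep, "kind": "sbp",
                                   "value": np.clip(values, 60, 250), "date_days": dates}))

    n_bmi = 1 + rng.poisson(0.5, n)
    rep = np.repeat(np.arange(n), n_bmi)
    dates = _spaced_dates(entry_days.to_numpy(), n_bmi, five_y - 1, rng)
    obs_parts.append(pd.DataFrame({"patient_id": rep, "kind": "bmi",
                                   "value": np.clip(rng.normal(bmi[rep], 0.6), 13, 60),
                                   "date_days": dates}))

    n_chol = 1 + rng.poisson(0.3, n)
    rep = np.repeat(np.arange(n), n_chol)
    dates = _spaced_dates(entry_days.to_numpy(), n_chol, 3 * DAYS_PER_YEAR, rng)
    tc = np.clip(rng.normal(tchol[rep], 0.3), 2.0, 15.0)
    hd = np.clip(rng.normal(hdl[rep], 0.08), 0.5, 3.5)
    obs_parts.append(pd.DataFrame({"patient_id": rep, "kind": "total_cholesterol",
                                   "value": tc, "date_days": dates}))
    obs_parts.append(pd.DataFrame({"patient_id": rep, "kind": "hdl_cholesterol",
                                   "value": hd, "date_days": dates}))

    dates = entry_days.to_numpy() - rng.random(n) * five_y
    obs_parts.append(pd.DataFrame({"patient_id": np.arange(n), "kind": "smoking_status",
                                   "value": smoking, "date_days": dates}))

    observations = pd.concat(obs_parts, ignore_index=True)
    observations["date"] = pd.to_datetime(observations.pop("date_days").astype(int), unit="D")
    observations = observations.sort_values(["patient_id", "kind", "date"], kind="stable").reset_index(drop=True)

    # ---- diagnoses ---------------------------------------------------------
    dx_parts = []

    def add_dx(pids, codes, source, dates):
        dx_parts.append(pd.DataFrame({"patient_id": pids, "code": codes,
                                      "source": source, "date": dates}))

    for flag, code in CONDITION_CODES.items():
        if flag == "ckd3":
            m = ckd3_only
        elif flag == "ckd4":
            m = ckd45 & split45
        elif flag == "ckd5":
            m = ckd45 & ~split45
        elif flag == "hypertension_dx":
            m = flags["treated_hypertension"]
        elif flag == "ed_diagnosis":
            m = flags["erectile_dysfunction"] & (rng.random(n) < 0.9)
        else:
            m = flags.get(flag)
            if m is None:
                continue
        if not m.any():
            continue
        d = entry_days.to_numpy()[m] - rng.integers(30, int(10 * DAYS_PER_YEAR), m.sum())
        add_dx(np.flatnonzero(m), code, "gp", pd.to_datetime(d, unit="D"))

    prior = rng.random(n) < config.prior_cvd_rate
    if prior.any():
        d = entry_days.to_numpy()[prior] - rng.integers(30, int(8 * DAYS_PER_YEAR), prior.sum())
        src = np.where(rng.random(prior.sum()) < 0.5, "gp", "hospital")
        codes = [
            SUBTYPE_CODES["read" if s == "gp" else "icd10"][st]
            for s, st in zip(src, subtype[prior])
        ]
        add_dx(np.flatnonzero(prior), codes, src, pd.to_datetime(d, unit="D"))

    if event.any():
        ev_ids = np.flatnonzero(event)
        odays = (outcome_date[event].astype("int64") // 86_400_000_000_000).to_numpy()
        u = rng.random(len(ev_ids))
        gp_only = u < config.gp_only_outcome_share
        mort_first = (u >= config.gp_only_outcome_share) & (u < config.gp_only_outcome_share + 0.05) | fatal[ev_ids]
        st = subtype[ev_ids]
        # GP record at the outcome date for gp-only cases
        m = gp_only
        if m.any():
            add_dx(ev_ids[m], [SUBTYPE_CODES["read"][s] for s in st[m]], "gp",
                   pd.to_datetime(odays[m], unit="D"))
        # mortality record (ICD-9 dialect inside the 1998-2000 window)
        m = mort_first & ~gp_only
        if m.any():
            dts = pd.to_datetime(odays[m], unit="D")
            icd9_win = (dts >= pd.Timestamp("1998-01-01")) & (dts <= pd.Timestamp("2000-12-31"))
            codes = [
                SUBTYPE_CODES["icd9" if w9 else "icd10"][s]
                for w9, s in zip(icd9_win, st[m])
            ]
            add_dx(ev_ids[m], codes, "mortality", dts)
        # hospital record, with a trailing GP record a month later
        m = ~gp_only & ~mort_first
        if m.any():
            add_dx(ev_ids[m], [SUBTYPE_CODES["icd10"][s] for s in st[m]], "hospital",
                   pd.to_datetime(odays[m], unit="D"))
            lag = rng.integers(7, 60, m.sum())
            add_dx(ev_ids[m], [SUBTYPE_CODES["read"][s] for s in st[m]], "gp",
                   pd.to_datetime(odays[m] + lag, unit="D"))

    diagnoses = pd.concat(dx_parts, ignore_index=True) if dx_parts else pd.DataFrame(
        columns=["patient_id", "code", "source", "date"]
    )
    diagnoses = diagnoses.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)

    # ---- prescriptions -----------------------------------------------------
    rx_parts = []

    def add_scripts(mask, drug_class, qualifying=True):
        """Script series ending within 28d of entry (qualifying) or not."""
        ids = np.flatnonzero(mask)
        if not len(ids):
            return
        counts = 2 + rng.poisson(4, len(ids))
        rep = np.repeat(ids, counts)
        rep_counts = np.repeat(counts, counts)
        # position within each patient's series: 0 = most recent
        pos = np.concatenate([np.arange(c)[::-1] for c in counts])
        last_gap = rng.integers(1, 28, len(ids)) if qualifying else rng.integers(40, 200, len(ids))
        gaps = np.repeat(last_gap, counts)
        dates = entry_days.to_numpy()[rep] - gaps - pos * rng.integers(25, 36, len(rep))
        rx_parts.append(pd.DataFrame({"patient_id": rep, "drug_class": drug_class,
                                      "date": pd.to_datetime(dates, unit="D")}))

    add_scripts(flags["corticosteroid"], "corticosteroid")
    add_scripts(flags["atypical_antipsychotic"], "atypical_antipsychotic")
    add_scripts(flags["treated_hypertension"], "antihypertensive")
    ed_rx = flags["erectile_dysfunction"] & (rng.random(n) < 0.35)
    add_scripts(ed_rx, "erectile_dysfunction_treatment")
    baseline_statin = rng.random(n) < config.baseline_statin_rate
    add_scripts(baseline_statin, "statin")
    post_statin = (~baseline_statin) & (rng.random(n) < config.post_statin_rate)
    if post_statin.any():
        ids = np.flatnonzero(post_statin)
        startd = entry_days.to_numpy()[ids] + rng.integers(180, int(6 * DAYS_PER_YEAR), len(ids))
        counts = 1 + rng.poisson(6, len(ids))
        rep = np.repeat(ids, counts)
        pos = np.concatenate([np.arange(c) for c in counts])
        dates = np.repeat(startd, counts) + pos * 30
        rx_parts.append(pd.DataFrame({"patient_id": rep, "drug_class": "statin",
                                      "date": pd.to_datetime(dates, unit="D")}))

    prescriptions = pd.concat(rx_parts, ignore_index=True) if rx_parts else pd.DataFrame(
        columns=["patient_id", "drug_class", "date"]
    )
    prescriptions = prescriptions.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)

    tables = {
        "patients": patients,
        "observations": observations,
        "diagnoses": diagnoses,
        "prescriptions": prescriptions,
    }
    return apply_missingness(tables, config.missingness_rates,
                             seed=np.random.default_rng(config.seed + 1).integers(2**31),
                             age_slope=config.age_missingness_slope)


def write_tables(tables: dict, outdir, config: SimulationConfig | None = None) -> None:
    """Write the four tables as CSV plus a JSON manifest of the config."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    if config is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(config.manifest(), fh, indent=2, default=str)


def read_tables(indir) -> dict:
    from pathlib import Path

    indir = Path(indir)
    date_cols = {
        "patients": ["date_of_birth", "registration_date", "deregistration_date",
                     "death_date", "practice_install_date", "last_upload_date"],
        "observations": ["date"],
        "diagnoses": ["date"],
        "prescriptions": ["date"],
    }
    out = {}
    for name, cols in date_cols.items():
        df = pd.read_csv(indir / f"{name}.csv")
        for c in cols:
            if c in df.columns:
                df[c] = pd.to_datetime(df[c])
        out[name] = df
    return out
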