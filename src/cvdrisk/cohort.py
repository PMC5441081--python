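"""Assemble an analysis-ready cohort from longitudinal primary-care tables.

Inputs are four tables (patients, observations, diagnoses, prescriptions)
shaped like a primary-care research database extract with linked hospital
and mortality records.  This module derives each patient's cohort entry and
exit dates, applies the sequential exclusions (no deprivation score, prior
cardiovascular disease, statin use at baseline) with an auditable ledger,
constructs the baseline predictor vector, ascertains the composite
cardiovascular outcome across the three record sources, and tabulates
incidence.

Date arithmetic is in integer days with half-open follow-up [entry, exit);
years are days / 365.25.  Entry is the latest of the 25th birthday,
registration + 1 year, practice-system installation + 1 year and the study
start; exit is the earliest of the outcome, death, deregistration, last data
upload and study end, with the outcome winning ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_YEAR = 365.25

CVD_SUBTYPES = ("MI", "angina", "TIA", "ischaemic stroke")

DRUG_CLASSES = (
    "statin",
    "corticosteroid",
    "atypical_antipsychotic",
    "antihypertensive",
    "erectile_dysfunction_treatment",
)

#: binary condition flags carried into the cohort row
CONDITION_FLAGS = (
    "fh_chd",
    "type1_diabetes",
    "type2_diabetes",
    "hypertension_dx",
    "rheumatoid_arthritis",
    "atrial_fibrillation",
    "ckd3",
    "ckd4",
    "ckd5",
    "migraine",
    "sle",
    "severe_mental_illness",
    "hiv_aids",
    "ed_diagnosis",
)


# ---------------------------------------------------------------------------
# Code lists
# ---------------------------------------------------------------------------

class CodeList:
    """Prefix-matched mapping (code, dialect) -> condition [+ CVD subtype].

    Dialects: 'read' (GP records), 'icd10' (hospital + mortality), 'icd9'
    (mortality 1998-2000 only).  Matching is by code prefix, the convention
    of ICD chapter coding (I219 matches I21).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"code", "dialect", "condition"}
        if not required <= set(table.columns):
            raise ValueError(f"code list needs columns {sorted(required)}")
        if "subtype" not in table.columns:
            table = table.assign(subtype=None)
        self.table = table.reset_index(drop=True)

    @classmethod
    def default(cls) -> "CodeList":
        rows = []

        def add(codes, dialect, condition, subtype=None):
            for c in codes:
                rows.append((c, dialect, condition, subtype))

        # composite cardiovascular outcome
        add(["G45"], "icd10", "cvd", "TIA")
        add(["I20", "I24", "I25"], "icd10", "cvd", "angina")
        add(["I21", "I22", "I23"], "icd10", "cvd", "MI")
        add(["I63", "I64"], "icd10", "cvd", "ischaemic stroke")
        add(["410"], "icd9", "cvd", "MI")
        add(["411", "412", "413", "414"], "icd9", "cvd", "angina")
        add(["434", "436"], "icd9", "cvd", "ischaemic stroke")
        # synthetic Read-style dialect used by the simulator
        add(["G30"], "read", "cvd", "MI")
        add(["G33"], "read", "cvd", "angina")
        add(["G65"], "read", "cvd", "TIA")
        add(["G64"], "read", "cvd", "ischaemic stroke")
        # baseline conditions (GP record only; synthetic codes)
        add(["12C2"], "read", "fh_chd")
        add(["C10E"], "read", "type1_diabetes")
        add(["C10F"], "read", "type2_diabetes")
        add(["G20"], "read", "hypertension_dx")
        add(["N040"], "read", "rheumatoid_arthritis")
        add(["G573"], "read", "atrial_fibrillation")
        add(["K053"], "read", "ckd3")
        add(["K054"], "read", "ckd4")
        add(["K055"], "read", "ckd5")
        add(["F26"], "read", "migraine")
        add(["N000"], "read", "sle")
        add(["E10"], "read", "severe_mental_illness")
        add(["A788"], "read", "hiv_aids")
        add(["ED01"], "read", "ed_diagnosis")
        return cls(pd.DataFrame(rows, columns=["code", "dialect", "condition", "subtype"]))

    @classmethod
    def from_csv(cls, path) -> "CodeList":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def match(self, codes: pd.Series, dialect: str, condition: str) -> pd.Series:
        """Boolean mask: code starts with any listed prefix for condition."""
        prefixes = tuple(
            self.table.loc[
                (self.table.dialect == dialect) & (self.table.condition == condition),
                "code",
            ]
        )
        if not prefixes:
            return pd.Series(False, index=codes.index)
        return codes.astype(str).str.startswith(prefixes)

    def subtype_of(self, code: str, dialect: str) -> str | None:
        sub = self.table[
            (self.table.dialect == dialect) & (self.table.condition == "cvd")
        ]
        for _, row in sub.iterrows():
            if str(code).startswith(row.code):
                return row.subtype
        return None


# ---------------------------------------------------------------------------
# Exclusion ledger
# ---------------------------------------------------------------------------

@dataclass
class ExclusionLedger:
    """Sequential exclusion counts; conserves identified = included + drops."""

    identified: int
    missing_townsend: int
    prior_cvd: int
    baseline_statin: int
    # counted before 'identified' (age out of range / zero follow-up rows)
    out_of_age_range: int = 0
    zero_followup: int = 0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"negative ledger count: {name}")
        if self.included < 0:
            raise ValueError("exclusions exceed identified patients")

    @property
    def included(self) -> int:
        return (
            self.identified
            - self.missing_townsend
            - self.prior_cvd
            - self.baseline_statin
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["included"] = self.included
        return d


# ---------------------------------------------------------------------------
# Per-patient reference operations
# ---------------------------------------------------------------------------

def compute_entry_date(patient, study_start) -> pd.Timestamp:
    """Latest of 25th birthday, registration+1y, installation+1y, study start."""
    dob = pd.Timestamp(patient["date_of_birth"])
    reg = pd.Timestamp(patient["registration_date"])
    install = pd.Timestamp(patient["practice_install_date"])
    return max(
        dob + pd.DateOffset(years=25),
        reg + pd.DateOffset(years=1),
        install + pd.DateOffset(years=1),
        pd.Timestamp(study_start),
    )


def compute_exit_date(patient, outcome_date, study_end) -> tuple[pd.Timestamp, bool]:
    """Earliest of outcome, death, deregistration, last upload, study end.

    The event flag is True iff the outcome date attains the minimum (an
    outcome tied with a censoring date counts as an event).
    """
    candidates = [pd.Timestamp(study_end)]
    for key in ("death_date", "deregistration_date", "last_upload_date"):
        v = patient.get(key)
        if v is not None and not pd.isna(v):
            candidates.append(pd.Timestamp(v))
    censor = min(candidates)
    if outcome_date is not None and not pd.isna(outcome_date):
        outcome = pd.Timestamp(outcome_date)
        if outcome <= censor:
            return outcome, True
    return censor, False


def compute_sbp_sd(observations: pd.DataFrame, entry_date) -> float:
    """Sample SD (n-1) of SBP readings in [entry-5y, entry); NaN if < 2."""
    entry = pd.Timestamp(entry_date)
    window_start = entry - pd.DateOffset(years=5)
    obs = observations[
        (observations["kind"] == "sbp")
        & (pd.to_datetime(observations["date"]) >= window_start)
        & (pd.to_datetime(observations["date"]) < entry)
    ]
    if len(obs) < 2:
        return float("nan")
    return float(obs["value"].astype(float).std(ddof=1))


def ascertain_outcome(
    diagnoses: pd.DataFrame,
    code_list: CodeList,
    entry_date,
    exit_limit=None,
) -> tuple[pd.Timestamp, str, str] | None:
    """Earliest qualifying cardiovascular record after entry.

    Returns (date, subtype, source) or None.  ICD-9 codes qualify only on
    mortality records dated 1998-2000; sources gp/hospital/mortality carry
    dialects read/icd10/icd10 respectively (icd9 in the mortality window).
    """
    qual = _qualifying_cvd_mask(diagnoses, code_list)
    dx = diagnoses[qual].copy()
    dx["date"] = pd.to_datetime(dx["date"])
    dx = dx[dx["date"] > pd.Timestamp(entry_date)]
    if exit_limit is not None:
        dx = dx[dx["date"] <= pd.Timestamp(exit_limit)]
    if dx.empty:
        return None
    dx = dx.sort_values(["date"], kind="stable")
    row = dx.iloc[0]
    dialect = _dialect_for(row["source"], row["date"])
    subtype = code_list.subtype_of(row["code"], dialect) or "angina"
    return row["date"], subtype, row["source"]


def _dialect_for(source, date) -> str:
    if source == "gp":
        return "read"
    if source == "mortality" and pd.Timestamp("1998-01-01") <= pd.Timestamp(date) <= pd.Timestamp("2000-12-31"):
        return "icd9"
    return "icd10"


def _qualifying_cvd_mask(diagnoses: pd.DataFrame, code_list: CodeList) -> pd.Series:
    """CVD mask over a diagnosis table, honouring the ICD-9 window rule."""
    src = diagnoses["source"]
    date = pd.to_datetime(diagnoses["date"])
    codes = diagnoses["code"]
    known = src.isin(["gp", "hospital", "mortality"])
    if not known.all():
        bad = diagnoses.loc[~known, "source"].unique()
        raise ValueError(f"unmapped diagnosis source(s): {list(bad)}")
    icd9_window = (
        (src == "mortality")
        & (date >= pd.Timestamp("1998-01-01"))
        & (date <= pd.Timestamp("2000-12-31"))
    )
    mask = pd.Series(False, index=diagnoses.index)
    mask |= (src == "gp") & code_list.match(codes, "read", "cvd")
    mask |= (src == "hospital") & code_list.match(codes, "icd10", "cvd")
    mask |= (src == "mortality") & ~icd9_window & code_list.match(codes, "icd10", "cvd")
    mask |= icd9_window & code_list.match(codes, "icd9", "cvd")
    return mask


# ---------------------------------------------------------------------------
# Vectorised cohort construction
# ---------------------------------------------------------------------------

def _entry_dates(patients: pd.DataFrame, study_start) -> pd.Series:
    dob = pd.to_datetime(patients["date_of_birth"])
    reg = pd.to_datetime(patients["registration_date"])
    install = pd.to_datetime(patients["practice_install_date"])
    cands = pd.concat(
        [
            dob + pd.DateOffset(years=25),
            reg + pd.DateOffset(years=1),
            install + pd.DateOffset(years=1),
            pd.Series(pd.Timestamp(study_start), index=patients.index),
        ],
        axis=1,
    )
    return cands.max(axis=1)


def _censor_dates(patients: pd.DataFrame, study_end) -> pd.Series:
    cands = pd.concat(
        [
            pd.to_datetime(patients.get("death_date")),
            pd.to_datetime(patients.get("deregistration_date")),
            pd.to_datetime(patients.get("last_upload_date")),
            pd.Series(pd.Timestamp(study_end), index=patients.index),
        ],
        axis=1,
    )
    return cands.min(axis=1)


def _drug_exposure(
    prescriptions: pd.DataFrame, entry: pd.Series, drug_class: str, window_days: int = 28
) -> pd.Series:
    """>=2 scripts of the class before entry, most recent within 28 days."""
    rx = prescriptions[prescriptions["drug_class"] == drug_class]
    if rx.empty:
        return pd.Series(False, index=entry.index)
    rx = rx.merge(entry.rename("entry"), left_on="patient_id", right_index=True)
    rx = rx[pd.to_datetime(rx["date"]) < rx["entry"]]
    if rx.empty:
        return pd.Series(False, index=entry.index)
    rx["date"] = pd.to_datetime(rx["date"])
    g = rx.groupby("patient_id")["date"]
    count = g.size()
    latest = g.max()
    entry_al = entry.reindex(count.index)
    ok = (count >= 2) & ((entry_al - latest).dt.days <= window_days)
    return ok.reindex(entry.index, fill_value=False)


def _any_script_before_entry(prescriptions, entry, drug_class) -> pd.Series:
    rx = prescriptions[prescriptions["drug_class"] == drug_class]
    if rx.empty:
        return pd.Series(False, index=entry.index)
    rx = rx.merge(entry.rename("entry"), left_on="patient_id", right_index=True)
    hit = rx[pd.to_datetime(rx["date"]) < rx["entry"]].groupby("patient_id").size() > 0
    return hit.reindex(entry.index, fill_value=False)


def _latest_obs_before(observations, entry, kind) -> pd.Series:
    obs = observations[observations["kind"] == kind]
    if obs.empty:
        return pd.Series(np.nan, index=entry.index, dtype=object)
    obs = obs.merge(entry.rename("entry"), left_on="patient_id", right_index=True)
    obs = obs.assign(date=pd.to_datetime(obs["date"]))
    obs = obs[obs["date"] < obs["entry"]]
    if obs.empty:
        return pd.Series(np.nan, index=entry.index, dtype=object)
    obs = obs.sort_values(["patient_id", "date"], kind="stable")
    last = obs.groupby("patient_id").tail(1).set_index("patient_id")["value"]
    return last.reindex(entry.index)


def _closest_chol(observations, entry, exit_dates, first_statin, kind) -> pd.Series:
    """Cholesterol rule: closest value to entry; post-entry values allowed
    only before the outcome/censoring date and before any statin script."""
    obs = observations[observations["kind"] == kind]
    if obs.empty:
        return pd.Series(np.nan, index=entry.index, dtype=float)
    obs = obs.merge(entry.rename("entry"), left_on="patient_id", right_index=True)
    obs = obs.merge(exit_dates.rename("exitd"), left_on="patient_id", right_index=True)
    obs = obs.merge(
        first_statin.rename("statin0"), left_on="patient_id", right_index=True, how="left"
    )
    obs = obs.assign(date=pd.to_datetime(obs["date"]))
    pre = obs["date"] < obs["entry"]
    post_ok = (
        (obs["date"] >= obs["entry"])
        & (obs["date"] < obs["exitd"])
        & (obs["statin0"].isna() | (obs["date"] < obs["statin0"]))
    )
    obs = obs[pre | post_ok]
    if obs.empty:
        return pd.Series(np.nan, index=entry.index, dtype=float)
    obs = obs.assign(absdiff=(obs["date"] - obs["entry"]).abs())
    obs = obs.sort_values(["patient_id", "absdiff", "date"], kind="stable")
    best = obs.groupby("patient_id").head(1).set_index("patient_id")["value"]
    return best.astype(float).reindex(entry.index)


def _sbp_sd_vector(observations, entry) -> pd.Series:
    obs = observations[observations["kind"] == "sbp"]
    if obs.empty:
        return pd.Series(np.nan, index=entry.index, dtype=float)
    obs = obs.merge(entry.rename("entry"), left_on="patient_id", right_index=True)
    obs = obs.assign(date=pd.to_datetime(obs["date"]))
    window_start = obs["entry"] - pd.DateOffset(years=5)
    obs = obs[(obs["date"] >= window_start) & (obs["date"] < obs["entry"])]
    g = obs.groupby("patient_id")["value"]
    sd = g.std(ddof=1)
    sd[g.size() < 2] = np.nan
    return sd.reindex(entry.index)


def _condition_flags(diagnoses, code_list, entry) -> pd.DataFrame:
    """Binary flags from the latest GP record strictly before entry."""
    gp = diagnoses[diagnoses["source"] == "gp"]
    flags = pd.DataFrame(False, index=entry.index, columns=list(CONDITION_FLAGS))
    if gp.empty:
        return flags
    gp = gp.merge(entry.rename("entry"), left_on="patient_id", right_index=True)
    gp = gp[pd.to_datetime(gp["date"]) < gp["entry"]]
    for cond in CONDITION_FLAGS:
        mask = code_list.match(gp["code"], "read", cond)
        ids = gp.loc[mask, "patient_id"].unique()
        flags.loc[flags.index.isin(ids), cond] = True
    return flags


def build_cohort(
    patients: pd.DataFrame,
    observations: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    code_list: CodeList | None = None,
    study_start="1998-01-01",
    study_end="2015-12-31",
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Full cohort assembly; returns (cohort table, exclusion ledger)."""
    code_list = code_list or CodeList.default()
    pts = patients.set_index("patient_id")
    # strip the index name so merges that keep a 'patient_id' column never
    # produce a frame where the label is ambiguous (bites on empty joins)
    entry = _entry_dates(pts, study_start).rename_axis(None)
    censor = _censor_dates(pts, study_end).rename_axis(None)

    dob = pd.to_datetime(pts["date_of_birth"])
    age = (entry - dob).dt.days / DAYS_PER_YEAR
    in_age = (age >= 25.0) & (age < 85.0)
    positive_fu = censor > entry
    out_of_age = int((~in_age).sum())
    zero_fu = int((in_age & ~positive_fu).sum())
    keep = in_age & positive_fu
    pts, entry, censor, age = pts[keep], entry[keep], censor[keep], age[keep]
    identified = int(keep.sum())

    # sequential exclusions in the printed order
    townsend_missing = pts["townsend"].isna()
    n_townsend = int(townsend_missing.sum())
    keep1 = ~townsend_missing

    cvd_mask = _qualifying_cvd_mask(diagnoses, code_list) & diagnoses["source"].isin(
        ["gp", "hospital"]
    )
    dx_cvd = diagnoses[cvd_mask].merge(
        entry.rename("entry"), left_on="patient_id", right_index=True
    )
    prior_ids = set(
        dx_cvd.loc[pd.to_datetime(dx_cvd["date"]) <= dx_cvd["entry"], "patient_id"]
    )
    prior = pd.Series(pts.index.isin(prior_ids), index=pts.index)
    n_prior = int((keep1 & prior).sum())
    keep2 = keep1 & ~prior

    statin = _drug_exposure(prescriptions, entry, "statin")
    n_statin = int((keep2 & statin).sum())
    keep3 = keep2 & ~statin

    ledger = ExclusionLedger(
        identified=identified,
        missing_townsend=n_townsend,
        prior_cvd=n_prior,
        baseline_statin=n_statin,
        out_of_age_range=out_of_age,
        zero_followup=zero_fu,
    )

    pts, entry, censor, age = pts[keep3], entry[keep3], censor[keep3], age[keep3]

    # outcome ascertainment: earliest qualifying record strictly after entry
    qual = _qualifying_cvd_mask(diagnoses, code_list)
    dx = diagnoses[qual & diagnoses["patient_id"].isin(pts.index)].copy()
    dx["date"] = pd.to_datetime(dx["date"])
    dx = dx.merge(entry.rename("entry"), left_on="patient_id", right_index=True)
    dx = dx[dx["date"] > dx["entry"]]
    dx = dx.sort_values(["patient_id", "date"], kind="stable")
    first_dx = dx.groupby("patient_id").head(1).set_index("patient_id")
    gp_any = (
        dx[dx["source"] == "gp"].groupby("patient_id")["date"].min()
    )
    nongp_any = (
        dx[dx["source"] != "gp"].groupby("patient_id")["date"].min()
    )
    outcome_date = first_dx["date"].reindex(pts.index)
    outcome_source = first_dx["source"].reindex(pts.index)
    subtypes = first_dx.apply(
        lambda r: code_list.subtype_of(r["code"], _dialect_for(r["source"], r["date"]))
        or "angina",
        axis=1,
    ) if len(first_dx) else pd.Series(dtype=object)
    outcome_subtype = subtypes.reindex(pts.index)
    gp_only = pd.Series(pts.index.isin(gp_any.index) & ~pts.index.isin(nongp_any.index), index=pts.index)

    event = outcome_date.notna() & (outcome_date <= censor)
    exit_date = censor.copy()
    exit_date[event] = outcome_date[event]
    outcome_date[~event] = pd.NaT
    outcome_subtype[~event] = None
    outcome_source[~event] = None
    gp_only &= event

    # baseline covariates
    statin_dates = prescriptions[prescriptions["drug_class"] == "statin"]
    first_statin = (
        statin_dates.assign(date=pd.to_datetime(statin_dates["date"]))
        .groupby("patient_id")["date"]
        .min()
        .reindex(pts.index)
        .rename_axis(None)
    )
    sbp = _latest_obs_before(observations, entry, "sbp").astype(float)
    bmi = _latest_obs_before(observations, entry, "bmi").astype(float)
    smoking = _latest_obs_before(observations, entry, "smoking_status")
    tchol = _closest_chol(observations, entry, exit_date, first_statin, "total_cholesterol")
    hdl = _closest_chol(observations, entry, exit_date, first_statin, "hdl_cholesterol")
    sbp_sd = _sbp_sd_vector(observations, entry)
    flags = _condition_flags(diagnoses, code_list, entry)

    cortico = _drug_exposure(prescriptions, entry, "corticosteroid")
    antipsy = _drug_exposure(prescriptions, entry, "atypical_antipsychotic")
    ed_rx = _drug_exposure(prescriptions, entry, "erectile_dysfunction_treatment")
    any_antihyp = _any_script_before_entry(prescriptions, entry, "antihypertensive")

    cohort = pd.DataFrame(
        {
            "patient_id": pts.index,
            "practice_id": pts["practice_id"].to_numpy(),
            "sex": pts["sex"].to_numpy(),
            "ethnicity": pts["ethnicity"].to_numpy(),
            "townsend": pts["townsend"].astype(float).to_numpy(),
            "entry_date": entry.to_numpy(),
            "exit_date": exit_date.to_numpy(),
            "event": event.to_numpy(),
            "outcome_date": outcome_date.to_numpy(),
            "outcome_subtype": outcome_subtype.to_numpy(),
            "outcome_source": outcome_source.to_numpy(),
            "gp_only": gp_only.to_numpy(),
            "age": age.to_numpy(),
            "smoking": smoking.to_numpy(),
            "sbp": sbp.to_numpy(),
            "sbp_sd": sbp_sd.to_numpy(),
            "bmi": bmi.to_numpy(),
            "total_cholesterol": tchol.to_numpy(),
            "hdl_cholesterol": hdl.to_numpy(),
        }
    )
    cohort["chol_ratio"] = cohort["total_cholesterol"] / cohort["hdl_cholesterol"]
    cohort["time"] = (
        (pd.to_datetime(cohort["exit_date"]) - pd.to_datetime(cohort["entry_date"])).dt.days
        / DAYS_PER_YEAR
    )
    for cond in CONDITION_FLAGS:
        cohort[cond] = flags[cond].to_numpy()
    cohort["ckd45"] = (cohort["ckd4"] | cohort["ckd5"]).astype(bool)
    cohort["ckd345"] = (cohort["ckd3"] | cohort["ckd45"]).astype(bool)
    cohort["treated_hypertension"] = (
        cohort["hypertension_dx"] & any_antihyp.to_numpy()
    ).astype(bool)
    cohort["corticosteroid"] = cortico.to_numpy()
    cohort["atypical_antipsychotic"] = antipsy.to_numpy()
    cohort["erectile_dysfunction"] = (
        (cohort["ed_diagnosis"] | ed_rx.to_numpy()) & (cohort["sex"] == "M")
    ).astype(bool)
    for c in CONDITION_FLAGS + ("ckd45", "ckd345", "treated_hypertension",
                                "corticosteroid", "atypical_antipsychotic",
                                "erectile_dysfunction", "event", "gp_only"):
        cohort[c] = cohort[c].astype(int)
    return cohort.reset_index(drop=True), ledger


def extract_baseline_covariates(
    patient: pd.Series | dict,
    observations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    code_list: CodeList | None = None,
    study_start="1998-01-01",
    study_end="2015-12-31",
) -> pd.Series:
    """Single-patient cohort row (delegates to the vectorised builder)."""
    pid = patient["patient_id"]
    pts = pd.DataFrame([dict(patient)])
    cohort, _ = build_cohort(
        pts,
        observations[observations["patient_id"] == pid],
        diagnoses[diagnoses["patient_id"] == pid],
        prescriptions[prescriptions["patient_id"] == pid],
        code_list,
        study_start,
        study_end,
    )
    if cohort.empty:
        raise ValueError(f"patient {pid} does not enter the cohort")
    return cohort.iloc[0]


def apply_exclusions(
    patients, observations, diagnoses, prescriptions, code_list=None, **kw
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Alias for build_cohort emphasising the exclusion ledger."""
    return build_cohort(patients, observations, diagnoses, prescriptions, code_list, **kw)


# ---------------------------------------------------------------------------
# Incidence table
# ---------------------------------------------------------------------------

DEFAULT_AGE_BANDS = [(a, a + 5) for a in range(25, 85, 5)]


def _poisson_ci(cases: int, person_years: float, level: float = 0.95):
    """Exact (Garwood) CI for a Poisson rate per 1000 person-years."""
    a = 1.0 - level
    lo = stats.chi2.ppf(a / 2, 2 * cases) / 2 if cases > 0 else 0.0
    hi = stats.chi2.ppf(1 - a / 2, 2 * (cases + 1)) / 2
    return 1000.0 * lo / person_years, 1000.0 * hi / person_years


def incidence_table(
    cohort: pd.DataFrame, age_bands=None, sexes=("F", "M")
) -> pd.DataFrame:
    """Cases, person-years and rate per 1000 with exact Poisson 95% CI.

    Age at entry assigns the band (bands closed on the left, open on the
    right); person-years do not migrate across bands.
    """
    age_bands = age_bands or DEFAULT_AGE_BANDS
    rows = []
    for sex in sexes:
        sub = cohort[cohort["sex"] == sex]
        for lo, hi in age_bands:
            cell = sub[(sub["age"] >= lo) & (sub["age"] < hi)]
            cases = int(cell["event"].sum())
            py = float(cell["time"].sum())
            if py == 0:
                rows.append((sex, f"{lo}-{hi - 1}", cases, py, np.nan, np.nan, np.nan))
                continue
            rate = 1000.0 * cases / py
            ci_lo, ci_hi = _poisson_ci(cases, py)
            rows.append((sex, f"{lo}-{hi - 1}", cases, py, rate, ci_lo, ci_hi))
        cases = int(sub["event"].sum())
        py = float(sub["time"].sum())
        rate = 1000.0 * cases / py if py else np.nan
        ci = _poisson_ci(cases, py) if py else (np.nan, np.nan)
        rows.append((sex, "total", cases, py, rate, *ci))
    return pd.DataFrame(
        rows,
        columns=["sex", "age_band", "cases", "person_years", "rate_per_1000", "ci_lo", "ci_hi"],
    )
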