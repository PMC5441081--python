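"""End-to-end orchestration: simulate -> build -> impute -> fit -> validate.

Fits the three sex-specific model variants:

* **A** -- the established predictor set: age, ethnicity, deprivation,
  systolic blood pressure, BMI, cholesterol ratio, 5-level smoking, family
  history of premature coronary disease, type 1/2 diabetes, treated
  hypertension, rheumatoid arthritis, atrial fibrillation and stage 4/5
  kidney disease.
* **B** -- A with stage 3-5 kidney disease replacing stage 4/5, plus the
  new candidates (migraine, corticosteroids, SLE, atypical antipsychotics,
  severe mental illness, HIV/AIDS, erectile dysfunction in men) screened by
  the retention rule: adjusted HR outside (0.90, 1.10) and p < 0.01.
* **C** -- B plus the standard deviation of repeated systolic blood
  pressure readings.

Practices (never patients) are split 3:1 into derivation and validation
sets.  Fractional-polynomial transforms for age and BMI are selected on
complete cases in the derivation cohort and frozen across imputations;
coefficients are Rubin-pooled across the five imputations and the baseline
survivor function is the average of the per-imputation Breslow estimates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import synthetic
from .cohort import CodeList, build_cohort, incidence_table
from .coxfp import (FittedModel, apply_retention_rule, fit_pooled, select_fp,
                    test_age_interactions)
from .engine import predict_risk_array, linear_predictor
from .impute import ImputationSpec, mice_impute
from .model import TermSpec, build_design_matrix
from .synthetic import ETHNICITIES, SMOKING_LEVELS, SimulationConfig, generate_population
from .validate import (calibration_table, d_statistic, harrell_c,
                       per_practice_c, pooled_performance, practice_meta_c,
                       reclassification)

log = logging.getLogger("cvdrisk")

QRISK2_FLAGS = (
    "fh_chd", "type1_diabetes", "type2_diabetes", "treated_hypertension",
    "rheumatoid_arthritis", "atrial_fibrillation",
)
NEW_CANDIDATES = (
    "migraine", "corticosteroid", "sle", "atypical_antipsychotic",
    "severe_mental_illness", "hiv_aids",
)


def split_practices(practice_ids, fraction: float = 0.75, seed: int = 0):
    """Seeded random split of practice ids (derivation, validation).

    The split is by practice, never by patient; the two sets are disjoint
    and exhaustive.  The derivation set gets floor(fraction * k) practices.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    ids = np.unique(np.asarray(practice_ids))
    if len(ids) < 4:
        raise ValueError("need at least 4 practices to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n_deriv = int(np.floor(fraction * len(ids)))
    return np.sort(perm[:n_deriv]), np.sort(perm[n_deriv:])


# ---------------------------------------------------------------------------
# Model term construction
# ---------------------------------------------------------------------------

def _continuous_term(variable: str, data: pd.DataFrame, selection=None) -> list[TermSpec]:
    """Terms for one continuous variable, centred at the derivation mean."""
    mean = float(data[variable].dropna().mean())
    if selection is None or selection.kind in ("linear", "none"):
        return [TermSpec(variable, "linear", center=mean)]
    return selection.terms(center_value=mean)


def model_terms(
    model_id: str,
    sex: str,
    data: pd.DataFrame,
    fp_selections: dict | None = None,
    extra_flags: tuple = (),
) -> list[TermSpec]:
    """Design terms for one model variant on one sex."""
    fp_selections = fp_selections or {}
    terms: list[TermSpec] = []
    terms += _continuous_term("age", data, fp_selections.get("age"))
    terms += _continuous_term("townsend", data)
    terms += _continuous_term("sbp", data)
    terms += _continuous_term("chol_ratio", data)
    terms += _continuous_term("bmi", data, fp_selections.get("bmi"))
    for lev in ETHNICITIES[1:]:
        terms.append(TermSpec("ethnicity", "dummy", level=lev))
    for lev in SMOKING_LEVELS[1:]:
        terms.append(TermSpec("smoking", "dummy", level=lev))
    for flag in QRISK2_FLAGS:
        terms.append(TermSpec(flag, "binary"))
    if model_id == "A":
        terms.append(TermSpec("ckd45", "binary"))
    else:
        terms.append(TermSpec("ckd345", "binary"))
        for flag in extra_flags:
            terms.append(TermSpec(flag, "binary"))
    if model_id == "C":
        terms += _continuous_term("sbp_sd", data)
    return terms


def _drop_constant_terms(terms: list[TermSpec], datasets) -> list[TermSpec]:
    """Remove terms constant in any of the completed datasets.

    Rare binary flags (and dummy levels) can be absent outright in smaller
    cohorts; a constant column makes the Cox information matrix singular.
    """
    if isinstance(datasets, pd.DataFrame):
        datasets = [datasets]
    kept = []
    for tm in terms:
        if any(np.nanstd(np.asarray(tm.column(df), dtype=float)) == 0.0 for df in datasets):
            log.info("dropping constant term %s", tm.name())
            continue
        kept.append(tm)
    return kept


def screen_new_candidates(
    datasets: list[pd.DataFrame],
    sex: str,
    data_ref: pd.DataFrame,
    fp_selections: dict,
    ties: str = "breslow",
) -> list[str]:
    """Fit the full model-B candidate list; apply the retention rule."""
    candidates = [
        c for c in list(NEW_CANDIDATES) + (["erectile_dysfunction"] if sex == "M" else [])
        if data_ref[c].std() > 0
    ]
    full = model_terms("B", sex, data_ref, fp_selections, extra_flags=tuple(candidates))
    full = _drop_constant_terms(full, datasets)
    fitted = fit_pooled(datasets, full, ties=ties, model_id="B_full", sex=sex)
    summary = fitted.summary()
    retained = []
    for cand in candidates:
        row = summary[summary["term"] == cand].iloc[0]
        if apply_retention_rule(row["hr"], row["p"], is_new=True):
            retained.append(cand)
    return retained


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    models: tuple = ("A", "B", "C")
    m: int = 5
    mice_cycles: int = 10
    split_fraction: float = 0.75
    split_seed: int = 1
    impute_seed: int = 2
    threshold: float = 0.10
    horizon: int = 10
    ties: str = "breslow"
    select_fp_vars: tuple = ("age", "bmi")
    age_interactions: bool = False
    study_start: str = "1998-01-01"
    study_end: str = "2015-12-31"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.manifest()
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        for k in ("models", "select_fp_vars"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(simulation=sim, **raw)


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def baseline_characteristics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-sex baseline summary shaped like a study Table 1."""
    rows = []
    for sex, sub in cohort.groupby("sex"):
        n = len(sub)
        rec = {
            "sex": sex,
            "n": n,
            "mean_age": sub["age"].mean(),
            "mean_townsend": sub["townsend"].mean(),
            "bmi_recorded_pct": 100 * sub["bmi"].notna().mean(),
            "chol_ratio_recorded_pct": 100 * sub["chol_ratio"].notna().mean(),
            "sbp_recorded_pct": 100 * sub["sbp"].notna().mean(),
            "sbp_sd_recorded_pct": 100 * sub["sbp_sd"].notna().mean(),
            "smoking_recorded_pct": 100 * sub["smoking"].notna().mean(),
            "complete_data_pct": 100
            * (
                sub["bmi"].notna() & sub["chol_ratio"].notna()
                & sub["sbp"].notna() & sub["smoking"].notna()
            ).mean(),
            "mean_bmi": sub["bmi"].mean(),
            "mean_sbp": sub["sbp"].mean(),
            "mean_sbp_sd": sub["sbp_sd"].mean(),
            "mean_chol_ratio": sub["chol_ratio"].mean(),
        }
        for flag in QRISK2_FLAGS + NEW_CANDIDATES + ("ckd45", "ckd345", "erectile_dysfunction"):
            rec[f"{flag}_pct"] = 100 * sub[flag].mean()
        rows.append(rec)
    return pd.DataFrame(rows)


def _complete_cases(df: pd.DataFrame, extra: tuple = ()) -> pd.DataFrame:
    cols = ["sbp", "bmi", "chol_ratio", "smoking"] + list(extra)
    return df.dropna(subset=[c for c in cols if c in df.columns])


# ---------------------------------------------------------------------------
# Derivation / validation stages
# ---------------------------------------------------------------------------

def derive_models(
    deriv_imputed: dict[str, list[pd.DataFrame]],
    deriv_cohort: pd.DataFrame,
    config: PipelineConfig,
) -> dict[str, dict[str, FittedModel]]:
    """Per-sex FP selection, candidate screening and pooled Cox fits."""
    fitted: dict[str, dict[str, FittedModel]] = {m: {} for m in config.models}
    for sex in ("F", "M"):
        datasets = deriv_imputed[sex]
        ref = datasets[0]
        # FP selection on recorded (complete-case) values, frozen thereafter
        cc = _complete_cases(deriv_cohort[deriv_cohort["sex"] == sex])
        fps = {}
        for var in config.select_fp_vars:
            sub = cc.dropna(subset=[var])
            if len(sub) < 200 or sub["event"].sum() < 10:
                continue
            adjust = sub["age"].to_numpy()[:, None] if var != "age" else None
            fps[var] = select_fp(
                sub[var].to_numpy(), sub["time"].to_numpy(),
                sub["event"].to_numpy(dtype=bool),
                adjust=adjust, variable=var, ties=config.ties,
            )
            log.info("FP selection %s/%s: %s %s", sex, var, fps[var].kind, fps[var].powers)
        retained = None
        for model_id in config.models:
            if model_id == "A":
                terms = model_terms("A", sex, ref, fps)
            else:
                if retained is None:
                    retained = screen_new_candidates(datasets, sex, ref, fps, config.ties)
                    log.info("retained new candidates (%s): %s", sex, retained)
                terms = model_terms(model_id, sex, ref, fps, extra_flags=tuple(retained))
                if config.age_interactions and retained:
                    age_mean = float(ref["age"].mean())
                    inter = test_age_interactions(
                        ref, ref["time"], ref["event"].astype(bool), terms,
                        retained, age_mean, ties=config.ties,
                    )
                    terms = terms + inter
            terms = _drop_constant_terms(terms, datasets)
            fitted[model_id][sex] = fit_pooled(
                datasets, terms, ties=config.ties, model_id=model_id, sex=sex,
                metadata={"n": len(ref), "events": int(ref["event"].sum())},
            )
            log.info("fitted model %s (%s): %d terms", model_id, sex, len(terms))
    return fitted


def validate_models(
    fitted: dict,
    valid_imputed: dict[str, list[pd.DataFrame]],
    config: PipelineConfig,
) -> dict:
    """Pooled D/R2/C, calibration, practice meta-analysis, reclassification."""
    out: dict = {"performance": {}, "calibration": {}, "meta": {}, "reclassification": {}}
    risks_by_model: dict[str, dict[str, np.ndarray]] = {}
    for model_id in config.models:
        out["performance"][model_id] = {}
        out["calibration"][model_id] = {}
        risks_by_model[model_id] = {}
        for sex in ("F", "M"):
            cs = fitted[model_id][sex].to_coefficient_set()
            datasets = valid_imputed[sex]
            dvals, dses, cvals, cses = [], [], [], []
            risk_stack = []
            for dfj in datasets:
                lp = linear_predictor(cs, dfj, clamp=False)
                t = dfj["time"].to_numpy(dtype=float)
                d = dfj["event"].to_numpy(dtype=bool)
                dv, dse = d_statistic(lp, t, d, ties=config.ties)
                cv, cse = harrell_c(t, d, lp, horizon=config.horizon)
                dvals.append(dv); dses.append(dse)
                cvals.append(cv); cses.append(cse)
                risk_stack.append(predict_risk_array(cs, dfj, t=config.horizon, clamp=False))
            perf = pooled_performance(dvals, dses, cvals, cses, horizon=config.horizon)
            out["performance"][model_id][sex] = perf
            mean_risk = np.mean(risk_stack, axis=0)
            risks_by_model[model_id][sex] = mean_risk
            df0 = datasets[0]
            out["calibration"][model_id][sex] = calibration_table(
                mean_risk, df0["time"], df0["event"].astype(bool), horizon=config.horizon,
            )
    # practice-level meta-analysis on the first listed model
    first = config.models[0]
    for sex in ("F", "M"):
        df0 = valid_imputed[sex][0]
        pc = per_practice_c(df0, risks_by_model[first][sex], horizon=config.horizon)
        if len(pc) >= 3:
            out["meta"][sex] = practice_meta_c(pc["c"], pc["variance"], pc["events"])
    # reclassification between consecutive model variants, sexes combined
    pairs = [(a, b) for a, b in zip(config.models[:-1], config.models[1:])]
    for a, b in pairs:
        rx = np.concatenate([risks_by_model[a][s] for s in ("F", "M")])
        ry = np.concatenate([risks_by_model[b][s] for s in ("F", "M")])
        tt = np.concatenate([valid_imputed[s][0]["time"].to_numpy() for s in ("F", "M")])
        dd = np.concatenate(
            [valid_imputed[s][0]["event"].to_numpy(dtype=bool) for s in ("F", "M")]
        )
        out["reclassification"][f"{a}:{b}"] = reclassification(
            rx, ry, tt, dd, threshold=config.threshold, horizon=config.horizon,
        )
    return out


IMPUTE_COLS = [
    "patient_id", "practice_id", "sex", "ethnicity", "townsend", "age",
    "time", "event", "smoking", "sbp", "sbp_sd", "bmi", "total_cholesterol",
    "hdl_cholesterol", "chol_ratio",
]


def impute_by_sex(cohort: pd.DataFrame, m: int, cycles: int, seed: int) -> dict:
    """Run chained equations separately in women and men."""
    flag_cols = [c for c in cohort.columns if c in (
        QRISK2_FLAGS + NEW_CANDIDATES + ("ckd45", "ckd345", "erectile_dysfunction"))]
    out = {}
    for i, sex in enumerate(("F", "M")):
        sub = cohort.loc[cohort["sex"] == sex, IMPUTE_COLS + flag_cols].reset_index(drop=True)
        spec = ImputationSpec(m=m, cycles=cycles, seed=seed + i)
        out[sex] = mice_impute(sub, spec)
    return out


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute every stage; return (and optionally write) the report bundle."""
    stage = "simulate"
    try:
        tables = generate_population(config.simulation)
        log.info("simulated %d patients, %d observations",
                 len(tables["patients"]), len(tables["observations"]))

        stage = "split"
        deriv_ids, valid_ids = split_practices(
            tables["patients"]["practice_id"], config.split_fraction, config.split_seed,
        )

        stage = "build"
        cohorts, ledgers = {}, {}
        for name, ids in (("derivation", deriv_ids), ("validation", valid_ids)):
            pts = tables["patients"][tables["patients"]["practice_id"].isin(ids)]
            keep = set(pts["patient_id"])
            cohorts[name], ledgers[name] = build_cohort(
                pts,
                tables["observations"][tables["observations"]["patient_id"].isin(keep)],
                tables["diagnoses"][tables["diagnoses"]["patient_id"].isin(keep)],
                tables["prescriptions"][tables["prescriptions"]["patient_id"].isin(keep)],
                CodeList.default(), config.study_start, config.study_end,
            )
            log.info("%s cohort: %s", name, ledgers[name].to_dict())

        stage = "impute"
        deriv_imp = impute_by_sex(cohorts["derivation"], config.m, config.mice_cycles,
                                  config.impute_seed)
        valid_imp = impute_by_sex(cohorts["validation"], config.m, config.mice_cycles,
                                  config.impute_seed + 100)

        stage = "fit"
        fitted = derive_models(deriv_imp, cohorts["derivation"], config)

        stage = "validate"
        results = validate_models(fitted, valid_imp, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "ledgers": {k: v.to_dict() for k, v in ledgers.items()},
        "baseline_characteristics": baseline_characteristics(cohorts["derivation"]),
        "incidence": incidence_table(cohorts["derivation"]),
        "cohorts": cohorts,
        "fitted": fitted,
        "results": results,
    }
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: dict, outdir) -> None:
    """Persist report tables (CSV), models and manifests (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": bundle["config_hash"], "config": bundle["config"],
            "ledgers": bundle["ledgers"]}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    bundle["baseline_characteristics"].to_csv(outdir / "baseline_characteristics.csv", index=False)
    bundle["incidence"].to_csv(outdir / "incidence.csv", index=False)
    for name, cohort in bundle["cohorts"].items():
        cohort.to_csv(outdir / f"cohort_{name}.csv", index=False)
    perf_rows = []
    for model_id, by_sex in bundle["results"]["performance"].items():
        for sex, perf in by_sex.items():
            perf_rows.append({"model": model_id, "sex": sex, **perf.to_dict()})
        for sex, cal in bundle["results"]["calibration"][model_id].items():
            cal.to_csv(outdir / f"calibration_{model_id}_{sex}.csv", index=False)
    pd.DataFrame(perf_rows).to_csv(outdir / "performance.csv", index=False)
    for model_id, by_sex in bundle["fitted"].items():
        for sex, fm in by_sex.items():
            fm.to_coefficient_set().save(outdir / f"coefficients_{model_id}_{sex}.json")
            fm.summary().to_csv(outdir / f"hazard_ratios_{model_id}_{sex}.csv", index=False)
    extras = {
        "meta": {s: m.to_dict() for s, m in bundle["results"]["meta"].items()},
        "reclassification": bundle["results"]["reclassification"],
    }
    with open(outdir / "validation_extras.json", "w") as fh:
        json.dump(extras, fh, indent=2, default=float)
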