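import numpy as np
import pandas as pd
import pytest

from cvdrisk import SimulationConfig, default_true_coefficients, generate_population
from cvdrisk.synthetic import (DEFAULT_MISSINGNESS, apply_missingness,
                               read_tables, simulate_event_times, write_tables)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_patients=0)
    with pytest.raises(ValueError):
        SimulationConfig(baseline_family="gamma")
    with pytest.raises(ValueError):
        SimulationConfig(missingness_rates={"bmi": {"F": 1.5, "M": 0.3}})


def test_generation_deterministic():
    cfg = SimulationConfig(n_patients=500, n_practices=5, seed=3)
    a = generate_population(cfg)
    b = generate_population(cfg)
    for k in a:
        pd.testing.assert_frame_equal(a[k], b[k])


def test_tables_schema(small_tables):
    pts = small_tables["patients"]
    for col in ("patient_id", "practice_id", "sex", "date_of_birth",
                "registration_date", "practice_install_date", "townsend", "ethnicity"):
        assert col in pts.columns
    assert pts["patient_id"].is_unique
    obs = small_tables["observations"]
    assert set(obs["kind"].unique()) <= {"sbp", "bmi", "total_cholesterol",
                                         "hdl_cholesterol", "smoking_status"}
    dx = small_tables["diagnoses"]
    assert set(dx["source"].unique()) <= {"gp", "hospital", "mortality"}
    rx = small_tables["prescriptions"]
    assert {"patient_id", "drug_class", "date"} <= set(rx.columns)


def test_event_times_inverse_cdf_closed_form():
    # With eta=0 and no censoring, T = scale * (-ln U)^(1/shape): the
    # empirical survivor function must match the Weibull closed form.
    rng_seed = 12
    n = 40_000
    eta = np.zeros(n)
    censor = np.full(n, np.inf)
    t, _ = simulate_event_times(eta, censor, "weibull", shape=1.2, scale=15.0, seed=rng_seed)
    for q in (5.0, 10.0, 20.0):
        expected = np.exp(-((q / 15.0) ** 1.2))
        assert np.mean(t > q) == pytest.approx(expected, abs=0.01)


def test_event_times_proportional_hazards():
    n = 60_000
    censor = np.full(n, np.inf)
    t0, _ = simulate_event_times(np.zeros(n), censor, "weibull", 1.2, 15.0, seed=1)
    t1, _ = simulate_event_times(np.full(n, np.log(2.0)), censor, "weibull", 1.2, 15.0, seed=2)
    # doubling the hazard doubles the cumulative hazard at any horizon
    h0 = -np.log(np.mean(t0 > 10.0))
    h1 = -np.log(np.mean(t1 > 10.0))
    assert h1 == pytest.approx(2.0 * h0, rel=0.05)


def test_event_times_nonfinite_eta_rejected():
    with pytest.raises(ValueError):
        simulate_event_times(np.array([0.0, np.inf]), np.full(2, np.inf),
                             "weibull", 1.2, 15.0, seed=0)


def test_missingness_rates_close_to_targets(small_tables, small_cohort):
    cohort, _ = small_cohort
    for var, col in (("bmi", "bmi"), ("smoking", "smoking"), ("sbp", "sbp")):
        for sex in ("F", "M"):
            target = DEFAULT_MISSINGNESS[var][sex]
            got = cohort.loc[cohort["sex"] == sex, col].isna().mean()
            assert got == pytest.approx(target, abs=0.05), (var, sex)


def test_missingness_correlated_within_patient(small_cohort):
    cohort, _ = small_cohort
    # shared propensity factor makes missingness positively correlated
    miss = cohort[["bmi", "sbp", "smoking"]].isna().astype(float)
    corr = miss.corr().to_numpy()
    off = corr[np.triu_indices_from(corr, k=1)]
    assert (off > 0.05).all()


def test_truth_coefficient_sets_valid():
    for sex in ("F", "M"):
        cs = default_true_coefficients(sex)
        assert cs.sex == sex
        assert len(cs.terms) == len(cs.coefficients) > 10
        assert 0 < cs.baseline_survival[10] < 1
    # erectile dysfunction only in the male equation
    vars_f = {t.variable for t in default_true_coefficients("F").terms}
    vars_m = {t.variable for t in default_true_coefficients("M").terms}
    assert "erectile_dysfunction" in vars_m - vars_f


def test_event_rate_realistic(small_cohort):
    cohort, _ = small_cohort
    rate = 1000.0 * cohort["event"].sum() / cohort["time"].sum()
    # the generator aims at the single-digit-per-1000-person-years regime
    assert 2.0 < rate < 25.0


def test_write_read_roundtrip(tmp_path, small_tables):
    cfg = SimulationConfig(n_patients=4000, n_practices=10, seed=42)
    write_tables(small_tables, tmp_path, cfg)
    back = read_tables(tmp_path)
    assert set(back) >= {"patients", "observations", "diagnoses", "prescriptions"}
    assert len(back["patients"]) == len(small_tables["patients"])
    assert (tmp_path / "manifest.json").exists()


def test_apply_missingness_removes_whole_kinds():
    rng = np.random.default_rng(0)
    n = 2000
    patients = pd.DataFrame({
        "patient_id": np.arange(n), "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        "townsend": rng.normal(size=n),
        "date_of_birth": pd.Timestamp("1960-01-01"),
    })
    obs = pd.DataFrame({
        "patient_id": np.repeat(np.arange(n), 2),
        "kind": ["bmi", "sbp"] * n,
        "date": "2005-01-01",
        "value": rng.normal(25, 3, 2 * n),
    })
    out = apply_missingness({"patients": patients, "observations": obs.copy()},
                            DEFAULT_MISSINGNESS, seed=5)
    kept = out["observations"]
    # per-patient all-or-nothing: each patient keeps 0 or all rows of a kind
    per = kept.groupby(["patient_id", "kind"]).size()
    assert per.isin([1]).all()
    frac_bmi_f = 1 - kept[kept["kind"] == "bmi"]["patient_id"].isin(
        patients.loc[patients["sex"] == "F", "patient_id"]
    ).pipe(lambda s: s.sum() / (patients["sex"] == "F").sum())
    assert frac_bmi_f == pytest.approx(DEFAULT_MISSINGNESS["bmi"]["F"], abs=0.05)
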