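import numpy as np
import pandas as pd
import pytest

from cvdrisk import ImputationSpec, mice_impute, nelson_aalen, pool_rubin


# ---------------------------------------------------------------------------
# Nelson-Aalen against a brute-force oracle
# ---------------------------------------------------------------------------

def _na_oracle(times, events):
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    out = np.zeros(len(t))
    uniq = np.unique(t[d])
    for i, ti in enumerate(t):
        h = 0.0
        for u in uniq[uniq <= ti]:
            n_at = np.sum(t >= u)
            h += np.sum(d & (t == u)) / n_at
        out[i] = h
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_nelson_aalen_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    t = rng.integers(1, 20, 60).astype(float)  # heavy ties
    d = rng.random(60) < 0.6
    np.testing.assert_allclose(nelson_aalen(t, d), _na_oracle(t, d), atol=1e-12)


# ---------------------------------------------------------------------------
# Rubin pooling arithmetic
# ---------------------------------------------------------------------------

def test_rubin_b_zero_means_t_equals_wbar():
    est = pool_rubin([2.0, 2.0, 2.0], [0.5, 0.7, 0.6])
    assert est.between_variance == 0.0
    assert est.total_variance == pytest.approx(est.within_variance) == pytest.approx(0.6)


def test_rubin_worked_example():
    # estimates {1, 3}, within variances {1, 1}:
    # Qbar=2, W=1, B=2, T = 1 + (1+1/2)*2 = 4
    est = pool_rubin([1.0, 3.0], [1.0, 1.0])
    assert est.point == pytest.approx(2.0)
    assert est.within_variance == pytest.approx(1.0)
    assert est.between_variance == pytest.approx(2.0)
    assert est.total_variance == pytest.approx(4.0)


def test_rubin_requires_two():
    with pytest.raises(ValueError):
        pool_rubin([1.0], [1.0])


def test_rubin_barnard_df_not_larger_than_dfcom():
    est = pool_rubin([1.0, 1.2, 0.9], [0.2, 0.25, 0.22], dfcom=50)
    assert est.df <= 50


# ---------------------------------------------------------------------------
# Chained-equation imputation
# ---------------------------------------------------------------------------

def _toy_cohort(n=600, miss=0.3, seed=3):
    rng = np.random.default_rng(seed)
    age = rng.uniform(30, 80, n)
    bmi = np.exp(np.log(26) + 0.004 * (age - 55) + rng.normal(0, 0.15, n))
    sbp = 125 + 0.4 * (age - 55) + rng.normal(0, 12, n)
    tc = rng.normal(5.5, 0.8, n).clip(2.5)
    hdl = rng.normal(1.4, 0.25, n).clip(0.6)
    smoking = rng.choice(["non", "former", "light", "moderate", "heavy"], n,
                         p=[0.5, 0.2, 0.1, 0.1, 0.1])
    time = rng.exponential(8, n).clip(0.1, 12)
    event = rng.random(n) < 0.15
    df = pd.DataFrame({
        "patient_id": np.arange(n), "practice_id": rng.integers(0, 5, n),
        "sex": "F", "ethnicity": "white_or_not_recorded",
        "townsend": rng.normal(0, 3, n), "age": age, "time": time,
        "event": event.astype(int), "smoking": smoking, "sbp": sbp,
        "sbp_sd": np.abs(rng.normal(9, 3, n)) + 0.5, "bmi": bmi,
        "total_cholesterol": tc, "hdl_cholesterol": hdl,
        "chol_ratio": tc / hdl, "fh_chd": rng.integers(0, 2, n),
    })
    for col in ("bmi", "sbp", "sbp_sd", "smoking", "total_cholesterol", "hdl_cholesterol"):
        df.loc[rng.random(n) < miss, col] = np.nan
    both = df["total_cholesterol"].isna() | df["hdl_cholesterol"].isna()
    df.loc[both, ["total_cholesterol", "hdl_cholesterol", "chol_ratio"]] = np.nan
    return df


def test_mice_fills_everything_and_preserves_observed():
    df = _toy_cohort()
    spec = ImputationSpec(m=2, cycles=3, seed=11)
    completed = mice_impute(df, spec)
    assert len(completed) == 2
    for out in completed:
        for col in ("bmi", "sbp", "smoking", "total_cholesterol", "hdl_cholesterol"):
            assert out[col].notna().all()
        obs = df["bmi"].notna()
        np.testing.assert_allclose(out.loc[obs, "bmi"], df.loc[obs, "bmi"])


def test_mice_pmm_imputes_observed_donor_values():
    df = _toy_cohort()
    completed = mice_impute(df, ImputationSpec(m=2, cycles=2, seed=5))
    donors = set(np.round(df["bmi"].dropna().to_numpy(), 10))
    filled = completed[0].loc[df["bmi"].isna(), "bmi"]
    assert set(np.round(filled.to_numpy(), 10)) <= donors


def test_mice_chol_ratio_recomputed():
    df = _toy_cohort()
    out = mice_impute(df, ImputationSpec(m=2, cycles=2, seed=7))[0]
    np.testing.assert_allclose(
        out["chol_ratio"], out["total_cholesterol"] / out["hdl_cholesterol"]
    )


def test_mice_no_missing_returns_copies():
    df = _toy_cohort(miss=0.0)
    completed = mice_impute(df, ImputationSpec(m=3, cycles=2, seed=1))
    assert len(completed) == 3
    pd.testing.assert_frame_equal(completed[0], completed[1])


def test_mice_all_missing_variable_rejected():
    df = _toy_cohort()
    df["bmi"] = np.nan
    with pytest.raises(ValueError):
        mice_impute(df, ImputationSpec(m=2, cycles=2, seed=1))


def test_mice_deterministic_given_seed():
    df = _toy_cohort()
    a = mice_impute(df, ImputationSpec(m=2, cycles=2, seed=9))
    b = mice_impute(df, ImputationSpec(m=2, cycles=2, seed=9))
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])


def test_mice_townsend_never_imputed():
    df = _toy_cohort()
    df.loc[0, "townsend"] = np.nan
    out = mice_impute(df, ImputationSpec(m=2, cycles=2, seed=2))[0]
    assert np.isnan(out.loc[0, "townsend"])


def test_mice_smoking_levels_valid():
    df = _toy_cohort()
    out = mice_impute(df, ImputationSpec(m=2, cycles=2, seed=4))[0]
    assert set(out["smoking"].unique()) <= {"non", "former", "light", "moderate", "heavy"}
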