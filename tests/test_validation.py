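import math

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from cvdrisk import (calibration_table, d_statistic, harrell_c, km_risk_at,
                     practice_meta_c, r2_d, reclassification)
from cvdrisk.validate import KAPPA, harrell_c_slow

from conftest import random_survival


# ---------------------------------------------------------------------------
# Harrell's C: fast implementation vs O(n^2) oracle
# ---------------------------------------------------------------------------

def test_c_fast_equals_slow_on_many_fixtures():
    rng = np.random.default_rng(100)
    for rep in range(110):
        n = int(rng.integers(5, 200))
        # heavy ties in both time and risk
        t = rng.integers(1, max(3, n // 4), n).astype(float)
        d = rng.random(n) < rng.uniform(0.2, 0.9)
        risk = np.round(rng.normal(size=n), 1)
        if d.sum() == 0:
            d[rng.integers(0, n)] = True
        horizon = float(rng.choice([10.0, np.inf, t.max() * 0.7]))
        fast, _ = harrell_c(t, d, risk, horizon=horizon, compute_se=False)
        slow = harrell_c_slow(t, d, risk, horizon=horizon)
        assert fast == pytest.approx(slow, abs=1e-12), f"rep {rep}"


def test_c_fast_equals_slow_large():
    rng = np.random.default_rng(101)
    t = rng.exponential(8, 2000)
    d = rng.random(2000) < 0.5
    risk = rng.normal(size=2000)
    fast, _ = harrell_c(t, d, risk, compute_se=False)
    slow = harrell_c_slow(t, d, risk)
    assert fast == pytest.approx(slow, abs=1e-12)


def test_c_perfect_and_random_orderings():
    t = np.arange(1.0, 101.0)
    d = np.ones(100, dtype=bool)
    risk = -t  # higher risk = shorter survival, perfectly concordant
    c, _ = harrell_c(t, d, risk, horizon=None, compute_se=False)
    assert c == pytest.approx(1.0)
    c2, _ = harrell_c(t, d, np.zeros(100), horizon=None, compute_se=False)
    assert c2 == pytest.approx(0.5)  # all tied risks count half


def test_c_horizon_truncation_changes_pairs():
    t = np.array([5.0, 15.0, 20.0])
    d = np.array([True, True, True])
    risk = np.array([3.0, 2.0, 1.0])
    full, _ = harrell_c(t, d, risk, horizon=None, compute_se=False)
    trunc, _ = harrell_c(t, d, risk, horizon=10.0, compute_se=False)
    assert full == pytest.approx(1.0)
    # after truncation only the t=5 event remains comparable
    assert trunc == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Royston-Sauerbrei D and R2_D
# ---------------------------------------------------------------------------

def test_d_approx_kappa_sigma_without_censoring():
    rng = np.random.default_rng(102)
    n = 10_000
    sigma = 1.3
    eta = rng.normal(0.0, sigma, n)
    t = rng.exponential(scale=np.exp(-eta))
    d = np.ones(n, dtype=bool)
    D, se = d_statistic(eta, t, d)
    assert D == pytest.approx(KAPPA * sigma, rel=0.05)
    assert se > 0


def test_r2_d_values_and_monotonicity():
    assert r2_d(0.0) == pytest.approx(0.0)
    grid = np.linspace(0.0, 5.0, 40)
    vals = [r2_d(x) for x in grid]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert r2_d(-2.0) == pytest.approx(r2_d(2.0))  # depends on |D|


def test_d_statistic_requirements():
    rng = np.random.default_rng(103)
    with pytest.raises(ValueError):
        d_statistic(rng.normal(size=5), rng.exponential(size=5), np.ones(5, dtype=bool))
    D, se = d_statistic(np.zeros(50), rng.exponential(size=50), np.ones(50, dtype=bool))
    assert D == 0.0 and math.isnan(se)


# ---------------------------------------------------------------------------
# Kaplan-Meier and calibration
# ---------------------------------------------------------------------------

def test_km_matches_lifelines():
    rng = np.random.default_rng(104)
    t = rng.exponential(12, 800)
    d = rng.random(800) < 0.6
    risk, lo, hi = km_risk_at(t, d, horizon=10.0)
    km = KaplanMeierFitter().fit(t, d)
    assert risk == pytest.approx(1.0 - km.predict(10.0), abs=1e-10)
    assert lo < risk < hi


def test_calibration_self_consistent_groups():
    rng = np.random.default_rng(105)
    n = 20_000
    pred = rng.uniform(0.01, 0.4, n)
    # simulate exactly the predicted 10-year risk with exponential times
    lam = -np.log(1.0 - pred) / 10.0
    t = rng.exponential(1.0 / lam)
    d = t <= 10.0
    t = np.minimum(t, 10.0)
    table = calibration_table(pred, t, d, horizon=10.0)
    assert len(table) == 10
    assert table["n"].sum() == n
    assert int(table["n"].max() - table["n"].min()) <= 1
    np.testing.assert_allclose(table["mean_predicted"], table["observed"], atol=0.02)
    assert table["mean_predicted"].is_monotonic_increasing


def test_calibration_constant_predictor_single_group():
    rng = np.random.default_rng(106)
    t = rng.exponential(8, 300)
    d = rng.random(300) < 0.4
    table = calibration_table(np.full(300, 0.1), t, d)
    assert len(table) == 1


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

def test_meta_tau2_zero_reduces_to_fixed_effect():
    c = np.array([0.80, 0.82, 0.81, 0.805])
    v = np.array([0.001, 0.002, 0.0015, 0.001])
    res = practice_meta_c(c, v)
    w = 1.0 / v
    fixed = np.sum(w * c) / np.sum(w)
    assert res.tau2 == 0.0
    assert res.i2 == 0.0
    assert res.summary == pytest.approx(fixed)


def test_meta_heterogeneity_detected_and_pi_wider_than_ci():
    rng = np.random.default_rng(107)
    true = rng.normal(0.8, 0.05, 30)
    v = np.full(30, 1e-4)
    obs = true + rng.normal(0, 0.01, 30)
    res = practice_meta_c(obs, v)
    assert res.tau2 > 0
    assert res.i2 > 50
    ci_w = res.ci[1] - res.ci[0]
    pi_w = res.prediction_interval[1] - res.prediction_interval[0]
    assert pi_w > ci_w


def test_meta_prediction_interval_coverage_under_frailty():
    rng = np.random.default_rng(108)
    cover = 0
    reps = 50
    for _ in range(reps):
        true = rng.normal(0.8, 0.03, 12)
        obs = true + rng.normal(0, 0.01, 12)
        res = practice_meta_c(obs, np.full(12, 1e-4))
        new = rng.normal(0.8, 0.03)
        lo, hi = res.prediction_interval
        cover += lo <= new <= hi
    assert cover / reps >= 0.85  # nominal 95%, generous tolerance


def test_meta_requires_two_practices():
    with pytest.raises(ValueError):
        practice_meta_c([0.8], [0.01])


# ---------------------------------------------------------------------------
# Reclassification
# ---------------------------------------------------------------------------

def test_reclassification_counts_conserved():
    rng = np.random.default_rng(109)
    n = 5000
    rx = rng.uniform(0, 0.3, n)
    ry = np.clip(rx + rng.normal(0, 0.02, n), 0, 1)
    t = rng.exponential(9, n)
    d = rng.random(n) < 0.2
    rep = reclassification(rx, ry, t, d, threshold=0.10)
    assert sum(rep["counts"].values()) == n
    n_high = rep["counts"]["high_high"] + rep["counts"]["high_low"]
    assert rep["pct_down_of_high_x"] == pytest.approx(
        100.0 * rep["counts"]["high_low"] / n_high
    )


def test_reclassification_threshold_inclusive():
    rep = reclassification([0.10], [0.0999], [5.0], [False], threshold=0.10)
    assert rep["counts"]["high_low"] == 1
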