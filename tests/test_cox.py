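import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from cvdrisk import ConvergenceError, SeparationError, fit_cox
from cvdrisk.coxfp import baseline_cumhaz, baseline_survivor

from conftest import random_survival


def test_three_subject_fixture_breslow():
    # one binary covariate; events at t=1 (x=1) and t=2 (x=0); analytic
    # score equation 2u^2 = 1 with u = exp(beta), so beta = -ln(2)/2
    X = np.array([[1.0], [0.0], [1.0]])
    t = np.array([1.0, 2.0, 3.0])
    d = np.array([True, True, False])
    res = fit_cox(X, t, d, ties="breslow")
    assert res.beta[0] == pytest.approx(-0.5 * np.log(2.0), abs=1e-10)


@pytest.mark.parametrize("ties", ["breslow", "efron"])
@pytest.mark.parametrize("seed,n,tie_grid", [(1, 500, None), (2, 2000, None), (3, 5000, 4)])
def test_matches_lifelines_to_4dp(ties, seed, n, tie_grid):
    rng = np.random.default_rng(seed)
    X, t, d, _ = random_survival(rng, n, p=3, tie_grid=tie_grid)
    res = fit_cox(X, t, d, ties=ties)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["T"], df["E"] = t, d
    # lifelines uses the Efron tie correction; Breslow coincides on tie-free data
    if ties == "breslow" and tie_grid is not None:
        return
    cph = CoxPHFitter()
    cph.fit(df, "T", "E", robust=False)
    np.testing.assert_allclose(res.beta, cph.params_.values, atol=1e-4)
    np.testing.assert_allclose(res.se, cph.standard_errors_.values, atol=1e-4)


def test_loglik_null_and_improvement():
    rng = np.random.default_rng(5)
    X, t, d, _ = random_survival(rng, 400)
    res = fit_cox(X, t, d)
    assert res.loglik >= res.loglik_null


def test_constant_column_rejected():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    d = np.array([True, True, False, True])
    X = np.column_stack([np.ones(4), [0.0, 1.0, 0.0, 1.0]])
    with pytest.raises(ValueError):
        fit_cox(X, t, d)


def test_collinear_design_rejected():
    rng = np.random.default_rng(6)
    x = rng.normal(size=200)
    X = np.column_stack([x, 2.0 * x])
    t = rng.exponential(size=200)
    d = np.ones(200, dtype=bool)
    with pytest.raises(ValueError):
        fit_cox(X, t, d)


def test_separation_detected():
    # perfect separation: the covariate orders survival times exactly
    n = 40
    t = np.arange(1.0, n + 1.0)
    d = np.ones(n, dtype=bool)
    X = t[:, None].copy()  # larger x -> longer survival, monotone likelihood
    with pytest.raises((SeparationError, ConvergenceError)):
        fit_cox(X, t, d)


def test_no_events_rejected():
    with pytest.raises(ValueError):
        fit_cox(np.zeros((3, 1)), np.arange(3.0) + 1, np.zeros(3, dtype=bool))


def test_scaling_invariance():
    rng = np.random.default_rng(7)
    X, t, d, _ = random_survival(rng, 600, p=2)
    res = fit_cox(X, t, d)
    res_scaled = fit_cox(X * np.array([1e4, 1e-3]), t, d)
    np.testing.assert_allclose(res_scaled.beta * np.array([1e4, 1e-3]), res.beta, rtol=1e-6)


def test_baseline_survivor_properties():
    rng = np.random.default_rng(8)
    X, t, d, _ = random_survival(rng, 800, p=2, censor_rate=0.2)
    t = t * 4.0  # spread over several "years"
    res = fit_cox(X, t, d)
    s0 = baseline_survivor(res.beta, X, t, d, years=range(1, 11))
    vals = [s0[y] for y in sorted(s0)]
    assert all(0 < v <= 1 for v in vals)
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


def test_baseline_cumhaz_matches_lifelines():
    rng = np.random.default_rng(9)
    X, t, d, _ = random_survival(rng, 500, p=2, censor_rate=0.2)
    res = fit_cox(X, t, d)
    times, H0 = baseline_cumhaz(res.beta, X, t, d)
    df = pd.DataFrame(X, columns=["a", "b"])
    df["T"], df["E"] = t, d
    cph = CoxPHFitter(baseline_estimation_method="breslow").fit(df, "T", "E")
    # lifelines' baseline is at the covariate MEAN; shift ours accordingly
    shift = np.exp(X.mean(axis=0) @ cph.params_.values)
    ll = cph.baseline_cumulative_hazard_["baseline cumulative hazard"]
    # H0 is a right-continuous step function; evaluate by step, not by line
    idx = np.searchsorted(times, ll.index.values[5:-5], side="right") - 1
    ours_at_mean = np.where(idx >= 0, H0[np.clip(idx, 0, None)], 0.0) * shift
    np.testing.assert_allclose(ours_at_mean, ll.values[5:-5], rtol=0.02)
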