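import numpy as np
import pytest

from cvdrisk import FP_POWERS, apply_retention_rule, select_fp
from cvdrisk.coxfp import _origin_shift
from cvdrisk.coxfp import test_age_interactions as screen_age_interactions
from cvdrisk.model import TermSpec

import pandas as pd


def _simulate_from_eta(rng, eta, censor_scale=3.0):
    t = rng.exponential(scale=np.exp(-eta))
    c = rng.exponential(scale=censor_scale, size=len(eta))
    return np.minimum(t, c), t <= c


def test_power_grid():
    assert FP_POWERS == (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def test_linear_effect_selects_linear():
    rng = np.random.default_rng(21)
    n = 4000
    x = rng.uniform(1.0, 3.0, n)
    times, events = _simulate_from_eta(rng, 0.8 * (x - 2.0))
    sel = select_fp(x, times, events)
    assert sel.kind in ("linear", "none")  # never a spurious FP at alpha=0.05... usually linear
    assert sel.kind == "linear"


def test_strong_nonlinear_effect_selects_fp():
    rng = np.random.default_rng(22)
    n = 6000
    x = rng.uniform(0.3, 4.0, n)
    times, events = _simulate_from_eta(rng, 2.0 / x - 1.0)  # true power -1
    sel = select_fp(x, times, events)
    assert sel.kind in ("fp1", "fp2")


def test_null_effect_mostly_drops_variable():
    rng = np.random.default_rng(23)
    hits = 0
    reps = 10
    for _ in range(reps):
        x = rng.uniform(1.0, 3.0, 800)
        eta = np.zeros(800)
        times, events = _simulate_from_eta(rng, eta)
        if select_fp(x, times, events).kind == "none":
            hits += 1
    # familywise alpha is 0.05, so false selection should be rare
    assert hits >= 7


def test_constant_variable_returns_none():
    rng = np.random.default_rng(24)
    x = np.full(100, 2.0)
    t = rng.exponential(size=100)
    sel = select_fp(x, t, np.ones(100, dtype=bool))
    assert sel.kind == "none"


def test_origin_shift_makes_positive():
    x = np.array([-3.0, 0.0, 2.0])
    s = _origin_shift(x)
    assert np.all(x + s > 0)
    assert _origin_shift(np.array([1.0, 2.0])) == 0.0


def test_selection_terms_round_trip():
    rng = np.random.default_rng(25)
    x = rng.uniform(0.5, 4.0, 5000)
    times, events = _simulate_from_eta(rng, 1.5 * np.log(x))
    sel = select_fp(x, times, events)
    terms = sel.terms(center_value=2.0)
    assert 1 <= len(terms) <= 2
    df = pd.DataFrame({sel.variable: np.array([2.0])})
    for tm in terms:
        assert tm.column(df)[0] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "hr,p,expected",
    [
        (1.25, 0.001, True),
        (0.80, 0.001, True),
        (1.05, 0.001, False),   # HR inside the indifference band
        (1.25, 0.02, False),    # not significant at 0.01
        (0.90, 0.001, False),   # boundary excluded
        (1.10, 0.001, False),
    ],
)
def test_retention_rule(hr, p, expected):
    assert apply_retention_rule(hr, p, is_new=True) is expected


def test_retention_rule_legacy_bypass():
    assert apply_retention_rule(1.0, 0.99, is_new=False) is True


def test_age_interaction_screen_finds_true_interaction():
    rng = np.random.default_rng(26)
    n = 6000
    age = rng.uniform(30.0, 80.0, n)
    flag = (rng.random(n) < 0.3).astype(float)
    eta = 0.03 * (age - 55.0) + flag * (0.9 - 0.04 * (age - 55.0))
    t = rng.exponential(scale=np.exp(-eta))
    c = rng.exponential(scale=3.0, size=n)
    df = pd.DataFrame({"age": age, "flag": flag})
    base = [TermSpec("age", center=55.0), TermSpec("flag", "binary")]
    inter = screen_age_interactions(df, np.minimum(t, c), t <= c, base, ["flag"], 55.0)
    assert len(inter) == 1 and inter[0].variable == "flag"


def test_age_interaction_screen_rejects_null():
    rng = np.random.default_rng(27)
    n = 4000
    age = rng.uniform(30.0, 80.0, n)
    flag = (rng.random(n) < 0.3).astype(float)
    eta = 0.03 * (age - 55.0) + 0.5 * flag
    t = rng.exponential(scale=np.exp(-eta))
    c = rng.exponential(scale=3.0, size=n)
    df = pd.DataFrame({"age": age, "flag": flag})
    base = [TermSpec("age", center=55.0), TermSpec("flag", "binary")]
    inter = screen_age_interactions(df, np.minimum(t, c), t <= c, base, ["flag"], 55.0)
    assert inter == []
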