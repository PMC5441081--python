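import numpy as np
import pandas as pd
import pytest

from cvdrisk import SimulationConfig, build_cohort, generate_population


@pytest.fixture(scope="session")
def small_tables():
    cfg = SimulationConfig(n_patients=4000, n_practices=10, seed=42)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_tables):
    cohort, ledger = build_cohort(
        small_tables["patients"],
        small_tables["observations"],
        small_tables["diagnoses"],
        small_tables["prescriptions"],
    )
    return cohort, ledger


def random_survival(rng, n, p=2, beta=None, censor_rate=0.3, tie_grid=None):
    """Random right-censored survival data for fitter tests."""
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = rng.normal(scale=0.5, size=p)
    eta = X @ beta
    t = rng.exponential(scale=np.exp(-eta))
    c = rng.exponential(scale=np.exp(-eta) / max(censor_rate, 1e-9)) if censor_rate else np.full(n, np.inf)
    times = np.minimum(t, c)
    events = t <= c
    if tie_grid:
        times = np.ceil(times * tie_grid) / tie_grid
    return X, times, events, np.asarray(beta, dtype=float)
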