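"""Multiple imputation with chained equations for the incomplete predictors.

Six variables can be incomplete in the analysis cohort: body mass index,
systolic blood pressure (SBP), the standard deviation of repeated SBP
readings, total cholesterol, HDL cholesterol, and 5-level smoking status.
The chained-equation model for each is conditioned on every other predictor
plus two survival-aware auxiliary terms: the Nelson-Aalen estimate of the
cumulative hazard at each subject's exit time and the event indicator.
Deprivation (Townsend) is never imputed -- missing Townsend is an exclusion.

Engines: predictive mean matching (k = 5 donors, approximate Bayesian draw
of the regression parameters) for continuous variables, imputed on the log
scale for configurably skewed ones; a bootstrap multinomial-logistic draw
for smoking.  Results across the m completed datasets are combined with
Rubin's rules (`pool_rubin`), with Barnard-Rubin small-sample degrees of
freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_IMPUTE_VARS = (
    "bmi",
    "sbp",
    "sbp_sd",
    "total_cholesterol",
    "hdl_cholesterol",
    "smoking",
)
DEFAULT_LOG_VARS = frozenset({"bmi", "sbp_sd", "total_cholesterol", "hdl_cholesterol"})

SMOKING_LEVELS = ("non", "former", "light", "moderate", "heavy")


# ---------------------------------------------------------------------------
# Nelson-Aalen cumulative hazard
# ---------------------------------------------------------------------------

def nelson_aalen(times, events) -> np.ndarray:
    """Per-subject Nelson-Aalen cumulative hazard evaluated at exit.

    H(t) = sum over event times t_i <= t of d_i / n_i, where d_i is the
    number of events and n_i the number at risk (time >= t_i).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    if t.shape != d.shape:
        raise ValueError("times and events must have equal length")
    n = len(t)
    order = np.argsort(t, kind="stable")
    ts, ds = t[order], d[order]
    # distinct times, counting events and at-risk sizes
    uniq, start = np.unique(ts, return_index=True)
    d_at = np.add.reduceat(ds.astype(int), start)
    n_at = n - start  # at risk = all with time >= this distinct time
    increments = np.where(n_at > 0, d_at / n_at, 0.0)
    H_at = np.cumsum(increments)
    idx = np.searchsorted(uniq, t, side="right") - 1
    return np.where(idx >= 0, H_at[np.clip(idx, 0, None)], 0.0)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    point: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    m: int
    ci: tuple[float, float] = (np.nan, np.nan)

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def pool_rubin(estimates, variances, dfcom: float = np.inf, alpha: float = 0.05) -> PooledEstimate:
    """Combine per-imputation estimates: Q-bar, W-bar, B, T = W + (1+1/m)B.

    Degrees of freedom follow Barnard-Rubin when a finite complete-data df
    ``dfcom`` is supplied, and the classic (m-1)(1+1/r)^2 formula otherwise.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape:
        raise ValueError("estimates and variances must have equal length")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2 imputations")
    qbar = q.mean()
    wbar = w.mean()
    b = q.var(ddof=1)
    t = wbar + (1.0 + 1.0 / m) * b
    if b == 0.0 or t == 0.0:
        df = np.inf if not np.isfinite(dfcom) else dfcom
    else:
        lam = (1.0 + 1.0 / m) * b / t
        df_old = (m - 1) / lam**2
        if np.isfinite(dfcom):
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    se = np.sqrt(t)
    if np.isfinite(df):
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    else:
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
    ci = (float(qbar - crit * se), float(qbar + crit * se))
    return PooledEstimate(
        point=float(qbar),
        within_variance=float(wbar),
        between_variance=float(b),
        total_variance=float(t),
        df=float(df),
        m=m,
        ci=ci,
    )


# ---------------------------------------------------------------------------
# MICE
# ---------------------------------------------------------------------------

@dataclass
class ImputationSpec:
    variables: tuple[str, ...] = DEFAULT_IMPUTE_VARS
    m: int = 5
    cycles: int = 10
    k_donors: int = 5
    log_transform: frozenset = DEFAULT_LOG_VARS
    seed: int = 0
    auxiliary: tuple[str, ...] = ()  # extra predictor columns beyond the defaults

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")


def _bayes_draw_ols(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Approximate Bayesian draw of OLS parameters (beta*, and beta-hat).

    sigma^2 drawn from its scaled inverse-chi-square posterior, beta* from
    N(beta_hat, sigma*^2 (X'X)^-1).  Ridge jitter guards rank deficiency.
    """
    from scipy.linalg import solve_triangular

    n, p = X.shape
    xtx = X.T @ X
    ridge = 1e-8 * max(np.trace(xtx) / p, 1.0)
    L = None
    for _ in range(6):  # escalate the jitter until the factorisation succeeds
        try:
            L = np.linalg.cholesky(xtx + ridge * np.eye(p))
            break
        except np.linalg.LinAlgError:
            ridge *= 1e3
    if L is None:
        raise np.linalg.LinAlgError("predictor cross-product not factorisable")
    xty = X.T @ y
    beta_hat = solve_triangular(L.T, solve_triangular(L, xty, lower=True), lower=False)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    s2 = float(resid @ resid) / dof
    sigma2_star = s2 * dof / rng.chisquare(dof)
    # beta* = beta_hat + sigma* L^-T z  has covariance sigma*^2 (X'X)^-1
    z = rng.standard_normal(p)
    beta_star = beta_hat + math.sqrt(sigma2_star) * solve_triangular(L.T, z, lower=False)
    return beta_star, beta_hat


def _pmm_impute(
    X: np.ndarray, y: np.ndarray, miss: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Predictive mean matching: fill y[miss] with observed donor values."""
    obs = ~miss
    beta_star, beta_hat = _bayes_draw_ols(X[obs], y[obs], rng)
    yhat_obs = X[obs] @ beta_hat
    yhat_mis = X[miss] @ beta_star
    order = np.argsort(yhat_obs, kind="stable")
    sorted_pred = yhat_obs[order]
    sorted_y = y[obs][order]
    pos = np.searchsorted(sorted_pred, yhat_mis)
    n_obs = len(sorted_pred)
    out = np.empty(miss.sum())
    # candidate window of k nearest predicted values around insertion point
    for i, p in enumerate(pos):
        lo = max(0, p - k)
        hi = min(n_obs, p + k)
        window = np.arange(lo, hi)
        dist = np.abs(sorted_pred[window] - yhat_mis[i])
        nearest = window[np.argsort(dist, kind="stable")[:k]]
        out[i] = sorted_y[rng.choice(nearest)]
    return out


def _multinomial_impute(
    X: np.ndarray, y: pd.Series, miss: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap multinomial-logistic draw for a categorical variable."""
    from sklearn.linear_model import LogisticRegression

    obs = ~miss
    Xo, yo = X[obs], y[obs].to_numpy()
    boot = rng.integers(0, len(yo), len(yo))
    Xb, yb = Xo[boot], yo[boot]
    if len(np.unique(yb)) < 2:
        return np.full(miss.sum(), yb[0], dtype=object)
    clf = LogisticRegression(max_iter=200, tol=1e-4, C=1e4)
    clf.fit(Xb, yb)
    probs = clf.predict_proba(X[miss])
    cum = probs.cumsum(axis=1)
    u = rng.random((miss.sum(), 1))
    choice = (u > cum).sum(axis=1)
    return clf.classes_[np.clip(choice, 0, len(clf.classes_) - 1)]


def _predictor_matrix(
    df: pd.DataFrame, target: str, impute_vars, aux_cols, log_vars
) -> np.ndarray:
    """Design matrix for one chained equation: everything except the target."""
    cols = [np.ones(len(df))]
    for v in impute_vars:
        if v == target:
            continue
        if v == "smoking":
            for lev in SMOKING_LEVELS[1:]:
                cols.append((df["smoking"].astype(str) == lev).astype(float).to_numpy())
        else:
            x = df[v].to_numpy(dtype=float)
            if v in log_vars:
                x = np.log(np.clip(x, 1e-6, None))
            cols.append(x)
    for c in aux_cols:
        cols.append(df[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    # standardise non-intercept columns for numerical stability; predictors
    # outside the imputation model (e.g. deprivation) may carry missing
    # values -- mean-fill them internally (zero after standardisation)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(X[:, 1:], axis=0)
        sd = np.nanstd(X[:, 1:], axis=0)
    mu = np.nan_to_num(mu)
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    X[:, 1:] = (X[:, 1:] - mu) / sd
    return np.nan_to_num(X)


def mice_impute(
    cohort: pd.DataFrame,
    spec: ImputationSpec,
    time_col: str = "time",
    event_col: str = "event",
) -> list[pd.DataFrame]:
    """Run chained equations; return ``spec.m`` completed copies of ``cohort``.

    Auxiliary predictors: age, sex, Townsend, all binary condition flags
    present, plus the Nelson-Aalen cumulative hazard and the event indicator.
    The cholesterol ratio column (``chol_ratio``), when present, is
    recomputed from the imputed components in every completed dataset.
    """
    rng = np.random.default_rng(spec.seed)
    df = cohort.reset_index(drop=True)
    impute_vars = [v for v in spec.variables if v in df.columns]
    miss_masks = {v: df[v].isna().to_numpy() for v in impute_vars}
    for v in impute_vars:
        if miss_masks[v].all():
            raise ValueError(f"variable {v!r} is 100% missing; chained equations cannot start")
    if not any(m.any() for m in miss_masks.values()):
        return [df.copy() for _ in range(spec.m)]

    df = df.copy()
    df["_na_cumhaz"] = nelson_aalen(df[time_col], df[event_col])
    df["_event_ind"] = df[event_col].astype(float)
    base_aux = ["_na_cumhaz", "_event_ind"]
    for c in ("age", "townsend"):
        if c in df.columns:
            base_aux.append(c)
    if "sex" in df.columns:
        df["_sex_m"] = (df["sex"].astype(str) == "M").astype(float)
        base_aux.append("_sex_m")
    reserved = {time_col, event_col, "patient_id", "practice_id", "chol_ratio"}
    flag_cols = [
        c
        for c in df.columns
        if c not in impute_vars
        and c not in base_aux
        and c not in reserved
        and not c.startswith("_")
        and pd.api.types.is_numeric_dtype(df[c])
        and df[c].dropna().isin([0, 1]).all()
    ]
    aux_cols = base_aux + flag_cols + [c for c in spec.auxiliary if c in df.columns]

    completed = []
    for imp in range(spec.m):
        work = df.copy()
        # initialise each missing slot with a random observed value
        for v in impute_vars:
            miss = miss_masks[v]
            if miss.any():
                donors = work.loc[~miss, v].to_numpy()
                work.loc[miss, v] = rng.choice(donors, miss.sum())
        for _cycle in range(spec.cycles):
            for v in impute_vars:
                miss = miss_masks[v]
                if not miss.any():
                    continue
                X = _predictor_matrix(work, v, impute_vars, aux_cols, spec.log_transform)
                if v == "smoking":
                    work.loc[miss, v] = _multinomial_impute(X, work[v].astype(str), miss, rng)
                else:
                    y = work[v].to_numpy(dtype=float)
                    if v in spec.log_transform:
                        y = np.log(np.clip(y, 1e-6, None))
                    filled = _pmm_impute(X, y, miss, spec.k_donors, rng)
                    if v in spec.log_transform:
                        filled = np.exp(filled)
                    work.loc[miss, v] = filled
        out = work.drop(columns=[c for c in work.columns if c.startswith("_")])
        if {"total_cholesterol", "hdl_cholesterol"} <= set(out.columns) and "chol_ratio" in out.columns:
            out["chol_ratio"] = out["total_cholesterol"] / out["hdl_cholesterol"]
        completed.append(out)
    return completed
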