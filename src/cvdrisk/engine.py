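"""Risk scoring: evaluate a CoefficientSet for arbitrary covariate inputs.

risk(t) = 1 - S0(t) ** exp(eta), where eta is the centred linear predictor.
Scoring demands complete inputs: the derivation-side imputation machinery is
never applied silently at prediction time.  Out-of-range continuous inputs
can be clamped to configurable plausibility ranges (a warning is emitted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model import CoefficientSet, build_design_matrix

#: default plausibility ranges for clamping, mirroring a deployed calculator
DEFAULT_CLAMP_RANGES: dict[str, tuple[float, float]] = {
    "sbp": (60.0, 250.0),
    "sbp_sd": (0.0, 50.0),
    "bmi": (12.0, 60.0),
    "chol_ratio": (1.0, 12.0),
    "age": (25.0, 84.0),
    "townsend": (-8.0, 12.0),
}


class MissingCovariateError(KeyError):
    """A required covariate is absent (or NaN) at scoring time."""


@dataclass
class RiskResult:
    risk: float
    horizon: int
    linear_predictor: float
    classification: str | None = None
    threshold: float | None = None


def _as_frame(covariates) -> pd.DataFrame:
    if isinstance(covariates, pd.DataFrame):
        return covariates
    if isinstance(covariates, Mapping):
        return pd.DataFrame({k: np.atleast_1d(v) for k, v in covariates.items()})
    raise TypeError("covariates must be a mapping or a DataFrame")


def _validate_and_clamp(
    frame: pd.DataFrame, required: set[str], clamp: bool, clamp_ranges: Mapping
) -> pd.DataFrame:
    missing = sorted(v for v in required if v not in frame.columns)
    if missing:
        raise MissingCovariateError(f"missing required covariates: {', '.join(missing)}")
    nan_cols = sorted(
        v
        for v in required
        if pd.api.types.is_numeric_dtype(frame[v]) and frame[v].isna().any()
    )
    if nan_cols:
        raise MissingCovariateError(
            f"required covariates contain missing values: {', '.join(nan_cols)}"
        )
    if not clamp:
        return frame
    frame = frame.copy()
    for var, (lo, hi) in clamp_ranges.items():
        if var in frame.columns and pd.api.types.is_numeric_dtype(frame[var]):
            col = frame[var].astype(float)
            out = (col < lo) | (col > hi)
            if out.any():
                warnings.warn(
                    f"{int(out.sum())} value(s) of {var!r} outside [{lo}, {hi}]; clamped",
                    stacklevel=3,
                )
                frame[var] = col.clip(lo, hi)
    return frame


def linear_predictor(
    coefficients: CoefficientSet,
    covariates,
    clamp: bool = True,
    clamp_ranges: Mapping = DEFAULT_CLAMP_RANGES,
) -> np.ndarray:
    """eta = sum_j beta_j * f_j(x) for each input row."""
    frame = _validate_and_clamp(
        _as_frame(covariates), coefficients.required_variables, clamp, clamp_ranges
    )
    X = build_design_matrix(frame, coefficients.terms)
    eta = X @ np.asarray(coefficients.coefficients, dtype=float)
    if not np.all(np.isfinite(eta)):
        bad = np.flatnonzero(~np.isfinite(eta))
        raise ValueError(f"non-finite linear predictor for rows {bad[:5].tolist()}")
    return eta


def predict_risk(
    coefficients: CoefficientSet,
    covariates,
    t: int = 10,
    threshold: float | None = None,
    clamp: bool = True,
) -> RiskResult | list[RiskResult]:
    """10-year (or t-year) risk 1 - S0(t)^exp(eta) per input row."""
    if t not in coefficients.baseline_survival:
        available = sorted(coefficients.baseline_survival)
        raise ValueError(f"horizon {t} not tabulated; available: {available}")
    eta = linear_predictor(coefficients, covariates, clamp=clamp)
    s0 = coefficients.baseline_survival[t]
    risks = 1.0 - s0 ** np.exp(eta)
    results = [
        RiskResult(
            risk=float(r),
            horizon=t,
            linear_predictor=float(e),
            classification=classify(float(r), threshold) if threshold is not None else None,
            threshold=threshold,
        )
        for r, e in zip(risks, eta)
    ]
    return results[0] if len(results) == 1 else results


def predict_risk_array(
    coefficients: CoefficientSet, covariates, t: int = 10, clamp: bool = True
) -> np.ndarray:
    """Vectorised risk column for batch scoring."""
    if t not in coefficients.baseline_survival:
        raise ValueError(f"horizon {t} not tabulated")
    eta = linear_predictor(coefficients, covariates, clamp=clamp)
    return 1.0 - coefficients.baseline_survival[t] ** np.exp(eta)


def classify(risk: float, threshold: float = 0.10) -> str:
    """'high' iff risk >= threshold (the threshold itself counts as high)."""
    if not 0.0 <= risk <= 1.0:
        raise ValueError(f"risk {risk} outside [0, 1]")
    return "high" if risk >= threshold else "low"
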