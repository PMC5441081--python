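"""Model term specifications and portable coefficient sets.

A fitted risk equation is a list of terms, each mapping one input variable
(possibly transformed by a fractional-polynomial power, possibly a dummy for
one level of a categorical, possibly interacted with transformed age) to a
single column of the design matrix, plus a Cox coefficient per term and a
baseline survivor function S0(t) tabulated at whole years.

The 10-year risk of a subject with linear predictor eta is
``1 - S0(10) ** exp(eta)``.  Continuous terms are centred (the centring
constant is subtracted *after* the transform), so the reference subject --
all binary flags zero, continuous variables at their centring values -- has
eta = 0 and risk ``1 - S0(t)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: fractional-polynomial power grid; 0 means natural log
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def fp_transform(x: np.ndarray, power: float, shift: float = 0.0) -> np.ndarray:
    """Evaluate one fractional-polynomial basis function x -> (x+shift)^p.

    Power 0 is the natural log.  ``shift`` is the origin shift applied when
    the raw variable is not strictly positive.
    """
    z = np.asarray(x, dtype=float) + shift
    if power == 0.0:
        return np.log(z)
    return np.power(z, power)


def fp_repeated_transform(x: np.ndarray, power: float, shift: float = 0.0) -> np.ndarray:
    """Second basis function for a repeated-power FP2: (x+shift)^p * log(x+shift)."""
    z = np.asarray(x, dtype=float) + shift
    base = np.log(z) if power == 0.0 else np.power(z, power)
    return base * np.log(z)


@dataclass
class TermSpec:
    """One design-matrix column.

    Parameters
    ----------
    variable
        Input variable name.
    kind
        'linear'      raw value
        'fp'          (x+shift)^power, power 0 = log
        'fp_repeated' (x+shift)^power * log(x+shift)
        'dummy'       indicator variable == level
        'binary'      variable used as a 0/1 flag directly
    power, shift
        Fractional-polynomial parameters (kind 'fp'/'fp_repeated').
    level
        Category level (kind 'dummy').
    center
        Constant subtracted after the transform.
    age_transform
        Optional dict {'kind','power','shift','center'} describing the age
        column this term is multiplied by (an age interaction).
    """

    variable: str
    kind: str = "linear"
    power: float | None = None
    shift: float = 0.0
    level: str | None = None
    center: float = 0.0
    age_transform: dict | None = None

    def column(self, data: Mapping[str, Any] | pd.DataFrame) -> np.ndarray:
        x = data[self.variable]
        if isinstance(x, pd.Series):
            x = x.to_numpy()
        if self.kind == "linear":
            col = np.asarray(x, dtype=float)
        elif self.kind == "fp":
            col = fp_transform(x, self.power, self.shift)
        elif self.kind == "fp_repeated":
            col = fp_repeated_transform(x, self.power, self.shift)
        elif self.kind == "dummy":
            col = (np.asarray(x).astype(str) == str(self.level)).astype(float)
        elif self.kind == "binary":
            col = np.asarray(x, dtype=float)
        else:  # pragma: no cover - guarded by construction
            raise ValueError(f"unknown term kind {self.kind!r}")
        col = col - self.center
        if self.age_transform is not None:
            at = self.age_transform
            age = data["age"]
            if isinstance(age, pd.Series):
                age = age.to_numpy()
            if at.get("kind", "linear") == "fp":
                acol = fp_transform(age, at["power"], at.get("shift", 0.0))
            else:
                acol = np.asarray(age, dtype=float)
            acol = acol - at.get("center", 0.0)
            col = col * acol
        return col

    def name(self) -> str:
        parts = [self.variable]
        if self.kind == "fp":
            parts.append(f"fp{self.power:g}")
        elif self.kind == "fp_repeated":
            parts.append(f"fp{self.power:g}log")
        elif self.kind == "dummy":
            parts.append(str(self.level))
        if self.age_transform is not None:
            parts.append("x_age")
        return ":".join(parts)


def build_design_matrix(
    data: pd.DataFrame, terms: Sequence[TermSpec]
) -> np.ndarray:
    """Stack term columns into an (n, p) float design matrix."""
    return np.column_stack([t.column(data) for t in terms]) if terms else np.empty((len(data), 0))


@dataclass
class CoefficientSet:
    """A deployable scoring model: terms + coefficients + S0(t) by year."""

    model_id: str  # 'A' | 'B' | 'C' (free-form for synthetic truth sets)
    sex: str  # 'F' | 'M' | 'all'
    terms: list[TermSpec] = field(default_factory=list)
    coefficients: list[float] = field(default_factory=list)
    baseline_survival: dict[int, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.coefficients):
            raise ValueError("terms and coefficients must have equal length")
        s_prev = 1.0
        for year in sorted(self.baseline_survival):
            s = self.baseline_survival[year]
            if not (0.0 < s <= 1.0):
                raise ValueError(f"S0({year}) = {s} outside (0, 1]")
            if s > s_prev + 1e-12:
                raise ValueError("baseline survival must be non-increasing")
            s_prev = s

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "model_id": self.model_id,
            "sex": self.sex,
            "terms": [asdict(t) for t in self.terms],
            "coefficients": list(map(float, self.coefficients)),
            "baseline_survival": {str(k): float(v) for k, v in self.baseline_survival.items()},
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        if d.get("schema_version", 1) != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {d.get('schema_version')}")
        return cls(
            model_id=d["model_id"],
            sex=d["sex"],
            terms=[TermSpec(**t) for t in d["terms"]],
            coefficients=[float(b) for b in d["coefficients"]],
            baseline_survival={int(k): float(v) for k, v in d["baseline_survival"].items()},
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- convenience ------------------------------------------------------
    @property
    def required_variables(self) -> set[str]:
        req = {t.variable for t in self.terms}
        if any(t.age_transform is not None for t in self.terms):
            req.add("age")
        return req

    def hazard_ratios(self) -> pd.DataFrame:
        """exp(beta) per term (no CIs; see coxfp.FittedModel for pooled CIs)."""
        return pd.DataFrame(
            {
                "term": [t.name() for t in self.terms],
                "coefficient": self.coefficients,
                "hazard_ratio": [math.exp(b) for b in self.coefficients],
            }
        )
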