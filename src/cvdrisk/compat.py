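"""Compatibility harness for externally published coefficient files.

The openly licensed implementation of the deployed QRISK3 calculator
publishes its coefficient values; this module can score the printed clinical
example profiles against any coefficient file saved in this package's
CoefficientSet JSON schema.  No published file is bundled (it must be
converted and supplied by the user), so the harness is exercised in the test
suite with a synthetic coefficient set instead.
"""

from __future__ import annotations

import pandas as pd

from .engine import predict_risk_array
from .model import CoefficientSet
from .published import CLINICAL_EXAMPLES

#: covariates every profile row is padded with when absent
_DEFAULT_FLAGS = (
    "fh_chd", "type1_diabetes", "type2_diabetes", "treated_hypertension",
    "rheumatoid_arthritis", "atrial_fibrillation", "ckd45", "ckd345",
    "migraine", "corticosteroid", "sle", "atypical_antipsychotic",
    "severe_mental_illness", "hiv_aids", "erectile_dysfunction",
)


def example_profiles(sex: str | None = None) -> pd.DataFrame:
    """The printed clinical example profiles as a scoring-ready frame."""
    rows = []
    for ex in CLINICAL_EXAMPLES:
        if sex is not None and ex["sex"] != sex:
            continue
        row = {k: v for k, v in ex.items() if k != "printed_risk_pct"}
        for flag in _DEFAULT_FLAGS:
            row.setdefault(flag, 0)
        row.setdefault("townsend", 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def score_examples(coefficients: CoefficientSet, horizon: int = 10) -> pd.DataFrame:
    """Score every printed example matching the coefficient set's sex."""
    profiles = example_profiles(coefficients.sex if coefficients.sex in ("F", "M") else None)
    risks = predict_risk_array(coefficients, profiles, t=horizon)
    out = profiles[["example", "sex", "age"]].copy()
    out["risk"] = risks
    out["risk_pct"] = (100.0 * risks).round(1)
    return out


def compare_to_printed(coefficients: CoefficientSet, horizon: int = 10) -> pd.DataFrame:
    """Scored risks side by side with the printed model risks (percent)."""
    scored = score_examples(coefficients, horizon)
    printed = {
        ex["example"]: ex["printed_risk_pct"].get(coefficients.model_id)
        for ex in CLINICAL_EXAMPLES
    }
    scored["printed_pct"] = scored["example"].map(printed)
    return scored
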