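import json

import numpy as np
import pandas as pd
import pytest

from cvdrisk import (CoefficientSet, TermSpec, build_design_matrix,
                     fp_repeated_transform, fp_transform)


def test_fp_transform_power_zero_is_log():
    x = np.array([1.0, np.e, np.e**2])
    np.testing.assert_allclose(fp_transform(x, 0.0), [0.0, 1.0, 2.0])


def test_fp_transform_powers_and_shift():
    x = np.array([4.0])
    np.testing.assert_allclose(fp_transform(x, -0.5), [0.5])
    np.testing.assert_allclose(fp_transform(x, 2.0), [16.0])
    np.testing.assert_allclose(fp_transform(x, 1.0, shift=1.0), [5.0])


def test_fp_repeated_transform():
    x = np.array([np.e])
    # x^1 * ln x at e = e
    np.testing.assert_allclose(fp_repeated_transform(x, 1.0), [np.e])
    # power 0: (ln x)^2
    np.testing.assert_allclose(fp_repeated_transform(x, 0.0), [1.0])


def test_termspec_centering_after_transform():
    data = pd.DataFrame({"bmi": [25.0]})
    term = TermSpec("bmi", "fp", power=0.0, center=np.log(25.0))
    np.testing.assert_allclose(term.column(data), [0.0], atol=1e-12)


def test_termspec_dummy_and_binary():
    data = pd.DataFrame({"smoking": ["non", "heavy"], "flag": [0, 1]})
    d = TermSpec("smoking", "dummy", level="heavy")
    np.testing.assert_allclose(d.column(data), [0.0, 1.0])
    b = TermSpec("flag", "binary")
    np.testing.assert_allclose(b.column(data), [0.0, 1.0])


def test_termspec_age_interaction_column():
    data = pd.DataFrame({"flag": [1, 1, 0], "age": [50.0, 40.0, 70.0]})
    term = TermSpec("flag", "binary", age_transform={"kind": "linear", "center": 45.0})
    np.testing.assert_allclose(term.column(data), [5.0, -5.0, 0.0])


def test_build_design_matrix_shape_and_order():
    data = pd.DataFrame({"age": [50.0, 60.0], "flag": [0, 1]})
    X = build_design_matrix(data, [TermSpec("age", center=55.0), TermSpec("flag", "binary")])
    np.testing.assert_allclose(X, [[-5.0, 0.0], [5.0, 1.0]])
    assert build_design_matrix(data, []).shape == (2, 0)


def _toy_set():
    return CoefficientSet(
        model_id="A", sex="F",
        terms=[TermSpec("age", center=45.0), TermSpec("flag", "binary")],
        coefficients=[0.05, 0.3],
        baseline_survival={5: 0.99, 10: 0.97},
    )


def test_coefficient_set_roundtrip(tmp_path):
    cs = _toy_set()
    path = tmp_path / "cs.json"
    cs.save(path)
    back = CoefficientSet.load(path)
    assert back.model_id == cs.model_id
    assert back.terms == cs.terms
    assert back.coefficients == cs.coefficients
    assert back.baseline_survival == cs.baseline_survival
    # plain JSON on disk
    json.loads(path.read_text())


def test_coefficient_set_validation():
    with pytest.raises(ValueError):
        CoefficientSet("A", "F", [TermSpec("age")], [0.1, 0.2], {10: 0.9})
    with pytest.raises(ValueError):
        CoefficientSet("A", "F", [], [], {10: 1.5})
    with pytest.raises(ValueError):
        CoefficientSet("A", "F", [], [], {5: 0.90, 10: 0.95})  # increasing S0


def test_required_variables_includes_age_for_interactions():
    cs = CoefficientSet(
        "B", "M",
        [TermSpec("flag", "binary", age_transform={"kind": "linear", "center": 45.0})],
        [0.1], {10: 0.95},
    )
    assert cs.required_variables == {"flag", "age"}


def test_hazard_ratios_table():
    hr = _toy_set().hazard_ratios()
    np.testing.assert_allclose(hr["hazard_ratio"], np.exp([0.05, 0.3]))
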