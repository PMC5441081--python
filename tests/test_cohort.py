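import numpy as np
import pandas as pd
import pytest

from cvdrisk import CodeList, ExclusionLedger, build_cohort, incidence_table
from cvdrisk.cohort import (ascertain_outcome, compute_entry_date,
                            compute_exit_date, compute_sbp_sd)


def test_entry_date_is_latest_of_four():
    patient = {
        "date_of_birth": "1960-06-15",
        "registration_date": "1999-03-01",
        "practice_install_date": "1995-01-01",
    }
    # registration + 1y (2000-03-01) dominates
    assert compute_entry_date(patient, "1998-01-01") == pd.Timestamp("2000-03-01")
    patient["date_of_birth"] = "1980-06-15"
    # 25th birthday (2005-06-15) dominates
    assert compute_entry_date(patient, "1998-01-01") == pd.Timestamp("2005-06-15")


def test_exit_date_outcome_wins_ties():
    patient = {"death_date": pd.Timestamp("2010-05-01")}
    date, event = compute_exit_date(patient, pd.Timestamp("2010-05-01"), "2015-12-31")
    assert event is True and date == pd.Timestamp("2010-05-01")
    date, event = compute_exit_date(patient, pd.Timestamp("2010-05-02"), "2015-12-31")
    assert event is False and date == pd.Timestamp("2010-05-01")
    date, event = compute_exit_date({}, None, "2015-12-31")
    assert event is False and date == pd.Timestamp("2015-12-31")


def test_sbp_sd_window_and_minimum_readings():
    obs = pd.DataFrame({
        "kind": ["sbp"] * 4,
        "date": ["2004-01-01", "2005-06-01", "2007-01-01", "2008-01-01"],
        "value": [120.0, 130.0, 140.0, 150.0],
    })
    # window [2003-01-01, 2008-01-01): three readings, excluding the entry-day one
    sd = compute_sbp_sd(obs, "2008-01-01")
    assert sd == pytest.approx(np.std([120.0, 130.0, 140.0], ddof=1))
    assert np.isnan(compute_sbp_sd(obs.iloc[:1], "2008-01-01"))


def test_ascertain_outcome_earliest_and_icd9_window():
    codes = CodeList.default()
    dx = pd.DataFrame({
        "code": ["G30..", "I21", "410"],
        "source": ["gp", "hospital", "mortality"],
        "date": ["2005-03-01", "2004-06-01", "1999-06-01"],
    })
    date, subtype, source = ascertain_outcome(dx, codes, "1998-06-01")
    # ICD-9 410 on a 1999 mortality record qualifies and is earliest
    assert date == pd.Timestamp("1999-06-01") and source == "mortality"
    # the same ICD-9 code outside the window does not qualify
    dx2 = dx.copy()
    dx2.loc[2, "date"] = "2003-06-01"
    date2, _, source2 = ascertain_outcome(dx2, codes, "1998-06-01")
    assert date2 == pd.Timestamp("2004-06-01") and source2 == "hospital"


def test_ascertain_outcome_none_before_entry():
    codes = CodeList.default()
    dx = pd.DataFrame({"code": ["I21"], "source": ["hospital"], "date": ["2000-01-01"]})
    assert ascertain_outcome(dx, codes, "2005-01-01") is None


def test_code_list_prefix_matching_and_roundtrip(tmp_path):
    codes = CodeList.default()
    assert codes.match(pd.Series(["I219"]), "icd10", "cvd").all()
    assert not codes.match(pd.Series(["I30"]), "icd10", "cvd").any()
    assert codes.subtype_of("G30..", "read") == "MI"
    path = tmp_path / "codes.csv"
    codes.to_csv(path)
    back = CodeList.from_csv(path)
    assert back.match(pd.Series(["G65zz"]), "read", "cvd").all()


def test_exclusion_ledger_conservation_and_validation():
    led = ExclusionLedger(1000, 10, 50, 40)
    assert led.included == 900
    assert led.to_dict()["included"] == 900
    with pytest.raises(ValueError):
        ExclusionLedger(100, 60, 50, 40)
    with pytest.raises(ValueError):
        ExclusionLedger(100, -1, 0, 0)


def test_build_cohort_ledger_and_flags(small_tables, small_cohort):
    cohort, ledger = small_cohort
    assert ledger.included == len(cohort)
    d = ledger.to_dict()
    assert d["included"] == d["identified"] - d["missing_townsend"] - d["prior_cvd"] - d["baseline_statin"]
    # ages within protocol range at entry
    assert cohort["age"].between(25, 85, inclusive="left").all()
    assert (cohort["time"] > 0).all()
    # derived flags are 0/1 ints
    for col in ("event", "fh_chd", "type2_diabetes", "treated_hypertension",
                "ckd45", "ckd345", "erectile_dysfunction"):
        assert set(cohort[col].unique()) <= {0, 1}
    # ckd45 implies ckd345
    assert (cohort["ckd45"] <= cohort["ckd345"]).all()
    # erectile dysfunction never flagged in women
    assert (cohort.loc[cohort["sex"] == "F", "erectile_dysfunction"] == 0).all()


def test_build_cohort_townsend_exclusion(small_tables):
    pts = small_tables["patients"].copy()
    pts["townsend"] = np.nan
    _, ledger = build_cohort(pts, small_tables["observations"],
                             small_tables["diagnoses"], small_tables["prescriptions"])
    assert ledger.included == 0
    assert ledger.missing_townsend == ledger.identified


def test_build_cohort_deterministic(small_tables):
    a, _ = build_cohort(small_tables["patients"], small_tables["observations"],
                        small_tables["diagnoses"], small_tables["prescriptions"])
    b, _ = build_cohort(small_tables["patients"], small_tables["observations"],
                        small_tables["diagnoses"], small_tables["prescriptions"])
    pd.testing.assert_frame_equal(a, b)


def test_incidence_table_definition(small_cohort):
    cohort, _ = small_cohort
    table = incidence_table(cohort)
    assert {"sex", "age_band", "cases", "person_years", "rate_per_1000"} <= set(table.columns)
    bands = table[table["age_band"] != "total"]
    assert bands["cases"].sum() == cohort["event"].sum()
    # per-sex totals match the band sums
    totals = table[table["age_band"] == "total"].set_index("sex")["cases"]
    for sex in ("F", "M"):
        assert totals[sex] == bands.loc[bands["sex"] == sex, "cases"].sum()
    # rate is cases / person-years, per 1000
    row = table[table["cases"] > 0].iloc[0]
    assert row["rate_per_1000"] == pytest.approx(1000.0 * row["cases"] / row["person_years"])
    assert (table["ci_lo"] <= table["rate_per_1000"] + 1e-9).all()
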