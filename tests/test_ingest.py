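"""Cleaning rules: dedup, role filtering, drug/event matching, units, bins."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tpopv.errors import ConfigurationError, FormatError
from tpopv.ingest import (DrugDictionary, SmqMap, bin_age, bin_duration,
                          bin_weight, build_clean_cases, deduplicate,
                          filter_by_role, map_events, match_drug,
                          normalize_age, normalize_weight, read_faers_tables,
                          write_faers_tables)


def _demo(rows):
    df = pd.DataFrame(rows, columns=["PRIMARYID", "CASEID", "FDA_DT"])
    for col in ["EVENT_DT", "AGE", "AGE_COD", "SEX", "WT", "WT_COD",
                "REPORTER_COUNTRY", "OCCP_COD"]:
        df[col] = ""
    return df.astype(str)


# --- deduplication ---------------------------------------------------------

def test_dedup_keeps_latest_fda_date():
    demo = _demo([("1", "A", "20230101"), ("2", "A", "20230301")])
    assert list(deduplicate(demo)["PRIMARYID"]) == ["2"]


def test_dedup_tie_broken_by_highest_primaryid():
    demo = _demo([("7", "B", "20230101"), ("9", "B", "20230101")])
    assert list(deduplicate(demo)["PRIMARYID"]) == ["9"]


def test_dedup_single_version_identity():
    demo = _demo([("5", "C", "20230101")])
    pd.testing.assert_frame_equal(deduplicate(demo), demo)


def test_dedup_partial_dates_sort_earliest():
    # '2023' (year only) orders before any complete 2023 date
    demo = _demo([("1", "A", "2023"), ("2", "A", "20230101")])
    assert list(deduplicate(demo)["PRIMARYID"]) == ["2"]


@given(st.lists(
    st.tuples(st.integers(1, 50),                      # primary id
              st.sampled_from(["A", "B", "C"]),        # case id
              st.sampled_from(["20230101", "20230301", "202301", "2023", ""])),
    min_size=1, max_size=12, unique_by=lambda t: t[0]))
def test_dedup_idempotent_and_order_invariant(rows):
    demo = _demo([(str(p), c, f) for p, c, f in rows])
    once = deduplicate(demo)
    pd.testing.assert_frame_equal(deduplicate(once), once)
    shuffled = demo.sample(frac=1, random_state=0).reset_index(drop=True)
    pd.testing.assert_frame_equal(deduplicate(shuffled), once)


# --- raw file round trip ---------------------------------------------------

def test_read_write_round_trip(tmp_path, planted_dataset):
    write_faers_tables(planted_dataset.tables, tmp_path)
    back = read_faers_tables(tmp_path)
    for name, df in planted_dataset.tables.items():
        assert len(back[name]) == len(df)
        assert back[name].attrs["n_malformed"] == 0


def test_read_missing_column_raises(tmp_path):
    (tmp_path / "DEMO.txt").write_text("PRIMARYID$CASEID\n1$A\n")
    for t in ["DRUG", "REAC", "THER"]:
        (tmp_path / f"{t}.txt").write_text("X\n")
    with pytest.raises(FormatError, match="FDA_DT"):
        read_faers_tables(tmp_path)


def test_read_rejects_wrong_field_count(tmp_path, planted_dataset):
    write_faers_tables(planted_dataset.tables, tmp_path)
    reac = tmp_path / "REAC.txt"
    reac.write_text(reac.read_text() + "1$2$extra$field\n")
    with pytest.warns(UserWarning, match="malformed"):
        back = read_faers_tables(tmp_path)
    assert back["REAC"].attrs["n_malformed"] == 1
    assert len(back["REAC"]) == len(planted_dataset.tables["REAC"])


def test_read_empty_table_with_header(tmp_path):
    from tpopv.ingest import REQUIRED_COLUMNS
    for t, cols in REQUIRED_COLUMNS.items():
        (tmp_path / f"{t}.txt").write_text("$".join(cols) + "\n")
    tables = read_faers_tables(tmp_path)
    assert all(len(df) == 0 for df in tables.values())
    assert all(df.attrs["n_malformed"] == 0 for df in tables.values())


# --- drug matching ---------------------------------------------------------

def test_match_drug_case_and_whitespace(drug_dict):
    assert match_drug("  ELTROMBOPAG ", drug_dict) == "Eltrombopag"
    assert match_drug("eltrombopag", drug_dict) == "Eltrombopag"


def test_match_drug_brand_name(drug_dict):
    assert match_drug("Promacta", drug_dict) == "Eltrombopag"
    assert match_drug("NPLATE", drug_dict) == "Romiplostim"
    assert match_drug("Doptelet", drug_dict) == "Avatrombopag"


def test_match_drug_no_substring_matching(drug_dict):
    assert match_drug("eltrombopag olamine tablet 50mg", drug_dict) is None
    assert match_drug("", drug_dict) is None


def test_dictionary_rejects_colliding_canonicals():
    with pytest.raises(ConfigurationError):
        DrugDictionary({"DrugA": {"x"}, "druga": {"y"}})


# --- event mapping ---------------------------------------------------------

def test_map_events_retains_mapped_pt(smq_map):
    out = map_events(["Pulmonary embolism", "Headache"], smq_map)
    assert out == [("Pulmonary embolism", "venous")]


def test_map_events_scope_rule():
    m = SmqMap({"Thrombosis narrow": ("venous", "narrow"),
                "Thrombosis broad": ("venous", "broad")})
    assert map_events(["Thrombosis broad"], m, scope="narrow") == []
    assert map_events(["Thrombosis broad"], m, scope="narrow+broad") == \
        [("Thrombosis broad", "venous")]


# --- unit normalization ----------------------------------------------------

@pytest.mark.parametrize("value,unit,expected", [
    (24, "MON", 2.0),
    (730, "DY", 730 / 365.25),
    (50, "YR", 50.0),
    (5.8, "DEC", 58.0),
    (104.355, "WK", 104.355 / 52.1775),
])
def test_normalize_age_units(value, unit, expected):
    assert normalize_age(value, unit) == pytest.approx(expected)


@pytest.mark.parametrize("value,unit", [(-3, "YR"), (150, "YR"), (10, "???")])
def test_normalize_age_invalid_is_missing_with_warning(value, unit):
    with pytest.warns(UserWarning):
        assert np.isnan(normalize_age(value, unit))


@pytest.mark.parametrize("value,unit,expected", [
    (70, "KG", 70.0),
    (220, "LBS", 220 * 0.45359237),
])
def test_normalize_weight_units(value, unit, expected):
    assert normalize_weight(value, unit) == pytest.approx(expected)


def test_normalize_weight_invalid(recwarn):
    with pytest.warns(UserWarning):
        assert np.isnan(normalize_weight(-5, "KG"))
    with pytest.warns(UserWarning):
        assert np.isnan(normalize_weight(70, "STONE"))


# --- binning convention ----------------------------------------------------

@pytest.mark.parametrize("age,group", [
    (0.5, "<18"), (17.99, "<18"), (18.0, "18-65"), (64.99, "18-65"),
    (65.0, "65-85"), (84.99, "65-85"), (85.0, ">85"), (101, ">85")])
def test_age_bins(age, group):
    assert bin_age([age]).iloc[0] == group


@pytest.mark.parametrize("wt,group", [
    (49.9, "<50"), (50.0, "50-100"), (100.0, "50-100"), (100.1, ">100")])
def test_weight_bins(wt, group):
    assert bin_weight([wt]).iloc[0] == group


@pytest.mark.parametrize("days,group", [
    (0, "<365"), (364, "<365"), (365, "365-730"), (730, "365-730"),
    (731, ">730")])
def test_duration_bins(days, group):
    assert bin_duration([days]).iloc[0] == group


def test_missing_maps_to_na_level():
    assert bin_age([np.nan]).isna().all()
    assert bin_weight([None]).isna().all()


# --- role filtering --------------------------------------------------------

def _mini_tables(drug_rows):
    """One case 'A' with the given (role, drugname) entries."""
    demo = _demo([("1", "A", "20230101")])
    drug = pd.DataFrame(
        [("1", "A", str(i + 1), role, name)
         for i, (role, name) in enumerate(drug_rows)],
        columns=["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"])
    reac = pd.DataFrame([("1", "A", "Pulmonary embolism")],
                        columns=["PRIMARYID", "CASEID", "PT"])
    ther = pd.DataFrame(columns=["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"])
    return {"DEMO": demo, "DRUG": drug.astype(str), "REAC": reac, "THER": ther}


def test_concomitant_only_target_excluded(drug_dict, smq_map):
    clean = build_clean_cases(_mini_tables([("C", "Promacta")]),
                              drug_dict, smq_map)
    assert clean.cases["case_class"].iloc[0] == "excluded_role"
    assert clean.analysis_cases.empty


def test_mixed_roles_same_drug_retained(drug_dict, smq_map):
    clean = build_clean_cases(_mini_tables([("PS", "Promacta"),
                                            ("C", "Eltrombopag")]),
                              drug_dict, smq_map)
    assert clean.cases["case_class"].iloc[0] == "target"
    assert clean.cases["target_drug"].iloc[0] == "Eltrombopag"


def test_ss_retained_when_allowed(drug_dict, smq_map):
    tables = _mini_tables([("SS", "Promacta")])
    assert build_clean_cases(tables, drug_dict, smq_map)\
        .cases["case_class"].iloc[0] == "excluded_role"
    assert build_clean_cases(tables, drug_dict, smq_map,
                             allowed_roles=("PS", "SS"))\
        .cases["case_class"].iloc[0] == "target"


def test_empty_allowed_roles_rejected(drug_dict, smq_map):
    with pytest.raises(ConfigurationError):
        build_clean_cases(_mini_tables([("PS", "Promacta")]), drug_dict,
                          smq_map, allowed_roles=())
    with pytest.raises(ConfigurationError):
        filter_by_role(pd.DataFrame({"target_drug": [], "target_role": []}),
                       allowed_roles=("XX",))


def test_non_target_drug_case_is_background(drug_dict, smq_map):
    clean = build_clean_cases(_mini_tables([("PS", "ASPIRIN")]),
                              drug_dict, smq_map)
    assert clean.cases["case_class"].iloc[0] == "background"
    assert clean.cases["target_drug"].isna().all()


# --- full pass on synthetic data ------------------------------------------

def test_count_conservation(clean_planted, planted_config):
    f = clean_planted.flow
    assert f["cases_after_dedup"] == planted_config.n_cases
    assert (f["target_cases"] + f["background_cases"] + f["excluded_by_role"]
            == f["cases_after_dedup"])


def test_selected_versions_match_ground_truth(clean_planted, planted_dataset):
    truth = planted_dataset.truth.cases
    merged = clean_planted.cases.merge(truth, on="case_id")
    assert len(merged) == len(truth)
    assert (merged["primary_id"] == merged["final_primary_id"]).all()


def test_target_drug_assignment_matches_truth(clean_planted, planted_dataset):
    """For PS-role TPO-RA cases, the matched drug equals the generator's."""
    truth = planted_dataset.truth.cases
    tpo = {"Avatrombopag", "Eltrombopag", "Romiplostim"}
    merged = clean_planted.cases.merge(truth, on="case_id")
    ps = merged[(merged["role"] == "PS") & merged["drug"].isin(tpo)]
    assert (ps["case_class"] == "target").all()
    assert (ps["target_drug"] == ps["drug"]).all()
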