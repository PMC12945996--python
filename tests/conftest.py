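import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tpopv.ingest import CleanCases
from tpopv.resources import default_drug_dictionary, default_smq_map
from tpopv.synthetic import GeneratorConfig, generate_reports

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def drug_dict():
    return default_drug_dictionary()


@pytest.fixture(scope="session")
def smq_map():
    return default_smq_map()


@pytest.fixture(scope="session")
def planted_config():
    """Small world with one strong known signal."""
    return GeneratorConfig(
        n_cases=4000, seed=11,
        planted_signals=(("Avatrombopag", "Deep vein thrombosis", 8.0),))


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    return generate_reports(planted_config)


@pytest.fixture(scope="session")
def clean_planted(planted_dataset, drug_dict, smq_map):
    from tpopv.ingest import build_clean_cases
    return build_clean_cases(planted_dataset.tables, drug_dict, smq_map)


def tiny_clean(case_rows, event_rows):
    """Hand-construct a CleanCases for enumeration-style tests.

    case_rows: list of (case_id, target_drug or None, case_class)
    event_rows: list of (case_id, pt, category)
    """
    columns = ["case_id", "primary_id", "fda_dt", "event_dt", "age_yr",
               "age_group", "sex", "wt_kg", "wt_group", "country", "reporter",
               "target_drug", "target_role", "start_dt", "n_reactions",
               "case_class"]
    cases = pd.DataFrame(
        [{"case_id": cid, "primary_id": f"{i}", "fda_dt": "20200101",
          "event_dt": "", "age_yr": np.nan, "age_group": pd.NA, "sex": pd.NA,
          "wt_kg": np.nan, "wt_group": pd.NA, "country": pd.NA,
          "reporter": pd.NA, "target_drug": drug,
          "target_role": "PS" if drug else pd.NA, "start_dt": pd.NA,
          "n_reactions": 1, "case_class": cls}
         for i, (cid, drug, cls) in enumerate(case_rows)],
        columns=columns)
    events = pd.DataFrame(event_rows, columns=["case_id", "pt", "category"])
    flow = {"versions_in": len(cases), "cases_after_dedup": len(cases),
            "target_cases": int((cases["case_class"] == "target").sum()),
            "background_cases": int((cases["case_class"] == "background").sum()),
            "excluded_by_role": int((cases["case_class"] == "excluded_role").sum()),
            "age_warnings": 0, "weight_warnings": 0}
    return CleanCases(cases=cases, events=events, flow=flow)
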