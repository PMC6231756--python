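"""Shared fixtures: published study tables and small synthetic inputs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

import reachra as rr

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

EXAMPLES = Path(__file__).resolve().parents[1] / "examples"

#: published per-year classified cohort totals (CI sample sizes n1)
COHORT_TOTALS = {2013: 33484, 2014: 18255, 2015: 5491, 2016: 1820, 2017: 8832}


@pytest.fixture(scope="session")
def cohort_percent() -> pd.DataFrame:
    return pd.read_csv(EXAMPLES / "cohort_strata_2013_2017.csv")


@pytest.fixture(scope="session")
def reference_percent() -> pd.DataFrame:
    return pd.read_csv(EXAMPLES / "reference_strata_2013_2017.csv")


@pytest.fixture(scope="session")
def reference_counts() -> pd.DataFrame:
    return pd.read_csv(EXAMPLES / "us_smokers_2013_2017.csv")


@pytest.fixture(scope="session")
def study_tables(cohort_percent, reference_percent):
    """(cohort, reference) StratumTables built from the published percentages."""
    cohort = rr.stratum_tables_from_percent(cohort_percent, COHORT_TOTALS)
    ref_totals = {
        y: 100.0 for y in reference_percent["year"].unique()
    }  # reference n unused by the fixed-reference interval
    reference = rr.stratum_tables_from_percent(reference_percent, ref_totals)
    return cohort, reference


@pytest.fixture()
def simple_crosswalk() -> rr.Crosswalk:
    """Tiny hand-wired crosswalk: one ZIP per stratum plus a straddling ZCTA."""
    return rr.Crosswalk(
        zip_to_zcta={"10001": "Z1", "20002": "Z2", "30003": "Z3", "40004": "Z4"},
        zcta_to_county={
            "Z1": (("01001", 1.0),),
            "Z2": (("02002", 1.0),),
            "Z3": (("03003", 1.0),),
            # straddles two counties; dominant county is Nonmetro
            "Z4": (("03003", 0.7), ("01001", 0.3)),
        },
        county_to_rucc={"01001": 1, "02002": 3, "03003": 7},
    )
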