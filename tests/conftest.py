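import numpy as np
import pandas as pd
import pytest

import faerspv as pv
from faerspv.ingest import CaseSet, RawTables, deduplicate

DRUG_GROUPS = [["durvalumab", "imfinzi"], ["tremelimumab", "imjudo"]]
FLAT_PATTERNS = [p for g in DRUG_GROUPS for p in g]


@pytest.fixture(scope="session")
def sim_data():
    """One moderate synthetic dataset shared across the suite."""
    cfg = pv.SyntheticConfig(n_background_reports=8000, seed=11)
    return pv.generate(cfg)


@pytest.fixture(scope="session")
def universe(sim_data):
    raw, _ = sim_data
    return deduplicate(raw)


@pytest.fixture(scope="session")
def cohort(universe):
    matched = pv.match_drug(universe, DRUG_GROUPS)
    return pv.filter_indication(matched, "hepatocellular carcinoma")


@pytest.fixture(scope="session")
def ledger(sim_data):
    return sim_data[1]


def make_caseset(case_pts: dict[str, list[str]],
                 extras: dict[str, dict] | None = None) -> CaseSet:
    """Minimal CaseSet: caseid -> PT list, optional per-case demo fields."""
    extras = extras or {}
    caseids = list(case_pts)
    demo = pd.DataFrame({
        "PRIMARYID": [c + "1" for c in caseids],
        "CASEID": caseids,
        "FDA_DT": [extras.get(c, {}).get("FDA_DT", "20240701") for c in caseids],
        "EVENT_DT": [extras.get(c, {}).get("EVENT_DT", "") for c in caseids],
        "SEX": [extras.get(c, {}).get("SEX", "") for c in caseids],
        "AGE": [extras.get(c, {}).get("AGE", "") for c in caseids],
        "AGE_COD": [extras.get(c, {}).get("AGE_COD", "") for c in caseids],
        "OCCP_COD": [extras.get(c, {}).get("OCCP_COD", "") for c in caseids],
        "REPORTER_COUNTRY": [extras.get(c, {}).get("REPORTER_COUNTRY", "X")
                             for c in caseids],
    })
    reac = pd.DataFrame(
        [(c + "1", c, pt) for c, pts in case_pts.items() for pt in pts],
        columns=["PRIMARYID", "CASEID", "PT"],
    )
    outc_rows = [
        (c + "1", c, code)
        for c in caseids
        for code in extras.get(c, {}).get("OUTC", [])
    ]
    outc = pd.DataFrame(outc_rows, columns=["PRIMARYID", "CASEID", "OUTC_COD"])
    empty = pd.DataFrame(columns=["PRIMARYID", "CASEID"])
    raw = RawTables(
        demo=demo,
        drug=pd.DataFrame(columns=["PRIMARYID", "CASEID", "DRUGNAME",
                                   "ROLE_COD"]),
        reac=reac,
        outc=outc,
        rpsr=empty.copy(),
        ther=pd.DataFrame(columns=["PRIMARYID", "CASEID", "START_DT"]),
        indi=pd.DataFrame(columns=["PRIMARYID", "CASEID", "INDI_PT"]),
    )
    return deduplicate(raw)


def table1_raw() -> RawTables:
    """Reconstruct the published demographic table as raw FAERS rows:
    715 reports with the published sex / age / occupation / outcome /
    country / year composition."""
    n = 715
    sexes = ["F"] * 75 + ["M"] * 348 + [""] * 292
    ages = ([("10", "YR")] * 15 + [("40", "YR")] * 96 + [("70", "YR")] * 244
            + [("85", "YR")] * 103 + [("", "")] * 257)
    occs = (["MD"] * 656 + ["PH"] * 17 + ["OT"] * 23 + ["CN"] * 7 + [""] * 12)
    outcomes = (["DE"] * 189 + ["DS"] * 1 + ["HO"] * 193 + ["LT"] * 75
                + ["OT"] * 176 + [None] * 81)
    countries = (["Japan"] * 510 + ["United States"] * 65 + ["France"] * 38
                 + ["China"] * 12 + ["Canada"] * 11
                 + ["Germany"] * 40 + ["Italy"] * 39)
    years = ([2020] * 52 + [2021] * 2 + [2022] * 3 + [2023] * 168
             + [2024] * 490)
    caseids = [str(100000 + i) for i in range(n)]
    demo = pd.DataFrame({
        "PRIMARYID": [c + "1" for c in caseids],
        "CASEID": caseids,
        "FDA_DT": [f"{y}0701" for y in years],
        "EVENT_DT": "",
        "SEX": sexes,
        "AGE": [a for a, _ in ages],
        "AGE_COD": [c for _, c in ages],
        "OCCP_COD": occs,
        "REPORTER_COUNTRY": countries,
    })
    outc = pd.DataFrame(
        [(c + "1", c, o) for c, o in zip(caseids, outcomes) if o],
        columns=["PRIMARYID", "CASEID", "OUTC_COD"],
    )
    empty = pd.DataFrame(columns=["PRIMARYID", "CASEID"])
    return RawTables(
        demo=demo,
        drug=pd.DataFrame(columns=["PRIMARYID", "CASEID", "DRUGNAME",
                                   "ROLE_COD"]),
        reac=pd.DataFrame(columns=["PRIMARYID", "CASEID", "PT"]),
        outc=outc,
        rpsr=empty.copy(),
        ther=pd.DataFrame(columns=["PRIMARYID", "CASEID", "START_DT"]),
        indi=pd.DataFrame(columns=["PRIMARYID", "CASEID", "INDI_PT"]),
    )


@pytest.fixture(scope="session")
def table1_cases():
    return deduplicate(table1_raw())
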