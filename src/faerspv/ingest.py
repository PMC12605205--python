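"""Reading, deduplication and cohort extraction for FAERS-format ASCII tables.

FAERS (the FDA Adverse Event Reporting System) distributes quarterly data as
seven ``$``-delimited ASCII tables: DEMO (demographics/administrative), DRUG,
REAC (reactions, MedDRA preferred terms), OUTC (outcomes), RPSR (report
sources), THER (therapy dates) and INDI (indications).  A *case* (``caseid``)
may be reported several times; each submission gets its own ``primaryid``.
All counting downstream is done on deduplicated cases.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("demo", "drug", "reac", "outc", "rpsr", "ther", "indi")

#: mandatory columns per table (FAERS ASCII schema, upper-case)
MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("PRIMARYID", "CASEID", "FDA_DT"),
    "drug": ("PRIMARYID", "CASEID", "DRUGNAME", "ROLE_COD"),
    "reac": ("PRIMARYID", "CASEID", "PT"),
    "outc": ("PRIMARYID", "CASEID", "OUTC_COD"),
    "rpsr": ("PRIMARYID", "CASEID"),
    "ther": ("PRIMARYID", "CASEID", "START_DT"),
    "indi": ("PRIMARYID", "CASEID", "INDI_PT"),
}

#: AGE_COD → multiplicative factor to years
AGE_UNIT_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.0,
    "HR": 1.0 / 8760.0,
}

MAX_PLAUSIBLE_AGE = 120.0

AGE_BINS = ("<18", "18-64", "65-79", ">=80")

OCCUPATION_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "health-professional",
    "HP": "health-professional",
    "RN": "health-professional",
    "CN": "consumer",
    "LW": "consumer",
}

#: serious-outcome categories as reported in demographic tables; OUTC_COD
#: CA (congenital anomaly) and RI (required intervention) are folded into
#: "Other serious outcomes".
OUTCOME_CATEGORIES = {
    "DE": "Death",
    "DS": "Disability",
    "HO": "Hospitalization",
    "LT": "Life-threatening events",
    "OT": "Other serious outcomes",
    "CA": "Other serious outcomes",
    "RI": "Other serious outcomes",
}

SERIOUS_CATEGORY_ORDER = (
    "Death",
    "Disability",
    "Hospitalization",
    "Life-threatening events",
    "Other serious outcomes",
)


# ---------------------------------------------------------------------------
# raw tables


@dataclass
class RawTables:
    """The seven FAERS tables of one (or a concatenation of several) quarters."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    rpsr: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def row_counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in TABLE_NAMES}


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame(columns=list(MANDATORY_COLUMNS[name]))


def parse_faers_date(raw: object) -> tuple[pd.Timestamp, str]:
    """Parse a FAERS date field into (timestamp, precision).

    FAERS dates are nominally 8-digit ``YYYYMMDD`` integers; partial dates
    (``YYYYMM``, ``YYYY``) occur and are kept with precision ``month`` /
    ``year`` (imputing mid-period), everything else is ``missing``.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return pd.NaT, "missing"
    s = str(raw).strip()
    if s.endswith(".0"):
        s = s[:-2]
    if not s or not s.isdigit():
        return pd.NaT, "missing"
    try:
        if len(s) == 8:
            return pd.Timestamp(int(s[:4]), int(s[4:6]), int(s[6:8])), "day"
        if len(s) == 6:
            return pd.Timestamp(int(s[:4]), int(s[4:6]), 15), "month"
        if len(s) == 4:
            return pd.Timestamp(int(s), 7, 1), "year"
    except ValueError:
        return pd.NaT, "missing"
    return pd.NaT, "missing"


def _parse_date_column(df: pd.DataFrame, col: str) -> pd.DataFrame:
    parsed = [parse_faers_date(v) for v in df[col]] if len(df) else []
    lower = col.lower()
    df = df.copy()
    if parsed:
        df[lower + "_date"] = [p[0] for p in parsed]
        df[lower + "_precision"] = [p[1] for p in parsed]
    else:
        df[lower + "_date"] = pd.Series(dtype="datetime64[ns]")
        df[lower + "_precision"] = pd.Series(dtype=object)
    return df


def _read_table(name: str, path: Path | str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        logger.warning("table %s: file %s absent, using empty table", name, path)
        return _empty_table(name)
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                     na_values=[""], engine="python")
    # tolerate trailing delimiters → unnamed empty columns
    df = df.loc[:, [c for c in df.columns if not c.startswith("Unnamed")]]
    df.columns = [c.strip().upper() for c in df.columns]
    if len(df) == 0:
        logger.warning("table %s: %s is empty", name, path)
    missing = [c for c in MANDATORY_COLUMNS[name] if c not in df.columns]
    if missing and len(df) > 0:
        raise ValueError(
            f"table {name!r} ({path}) lacks mandatory column(s): {missing}"
        )
    for c in MANDATORY_COLUMNS[name]:
        if c not in df.columns:
            df[c] = pd.Series(dtype=object)
    return df


def read_quarter(paths: Mapping[str, Path | str]) -> RawTables:
    """Read one quarter's FAERS ASCII tables.

    Parameters
    ----------
    paths
        Mapping from table name (``demo`` … ``indi``) to file path. Tables
        not mentioned (or whose file is absent) become empty with a warning;
        DEMO is required.
    """
    if "demo" not in paths:
        raise ValueError("a 'demo' table path is required")
    tables = {}
    for name in TABLE_NAMES:
        if name in paths:
            tables[name] = _read_table(name, paths[name])
        else:
            logger.warning("table %s not provided, using empty table", name)
            tables[name] = _empty_table(name)
    for name, col in (("demo", "EVENT_DT"), ("demo", "FDA_DT"),
                      ("ther", "START_DT")):
        df = tables[name]
        if col in df.columns or len(df) == 0:
            if col not in df.columns:
                df[col] = pd.Series(dtype=object)
            tables[name] = _parse_date_column(df, col)
    raw = RawTables(**tables)
    logger.info("read quarter: %s", raw.row_counts)
    return raw


def concat_quarters(quarters: Iterable[RawTables]) -> RawTables:
    """Stack several quarters' tables into one RawTables."""
    quarters = list(quarters)
    if not quarters:
        raise ValueError("no quarters given")
    merged = {
        name: pd.concat([q.table(name) for q in quarters], ignore_index=True)
        for name in TABLE_NAMES
    }
    return RawTables(**merged)


def write_quarter(raw: RawTables, out_dir: Path | str,
                  prefix: str = "") -> dict[str, Path]:
    """Write tables back out in the FAERS ``$``-delimited dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in TABLE_NAMES:
        df = raw.table(name)
        cols = [c for c in df.columns if c.isupper()]
        path = out_dir / f"{prefix}{name.upper()}.txt"
        df[cols].to_csv(path, sep="$", index=False)
        written[name] = path
    return written


# ---------------------------------------------------------------------------
# case-level views


@dataclass
class CaseReport:
    """One deduplicated case with its child records, for row-wise access."""

    caseid: str
    primaryid: str
    sex: str
    age_years: float | None
    age_group: str
    occupation: str
    country: str
    year: int | None
    outcomes: frozenset[str]
    drugs: list[tuple[str, str, object]]  # (name, role, start_date)
    events: list[str]
    indications: list[str]


@dataclass
class CaseSet:
    """Deduplicated case reports joined across the FAERS tables.

    ``cases`` has one row per case with normalised demographics; the child
    frames are restricted to the retained primaryids.  ``provenance`` records
    every filter applied, in order.
    """

    cases: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    therapies: pd.DataFrame
    indications: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def caseids(self) -> pd.Series:
        return self.cases["caseid"]

    def restrict(self, keep_caseids: Iterable[str], note: str) -> "CaseSet":
        keep = set(keep_caseids)
        cases = self.cases[self.cases["caseid"].isin(keep)].reset_index(drop=True)
        keep_pid = set(cases["primaryid"])

        def _sub(df: pd.DataFrame) -> pd.DataFrame:
            if "PRIMARYID" in df.columns and len(df):
                return df[df["PRIMARYID"].isin(keep_pid)].reset_index(drop=True)
            return df

        return CaseSet(
            cases=cases,
            drugs=_sub(self.drugs),
            reactions=_sub(self.reactions),
            outcomes=_sub(self.outcomes),
            therapies=_sub(self.therapies),
            indications=_sub(self.indications),
            provenance=self.provenance + [note],
        )

    def iter_reports(self) -> Iterator[CaseReport]:
        drugs_by = _group_by_pid(self.drugs)
        reac_by = _group_by_pid(self.reactions)
        indi_by = _group_by_pid(self.indications)
        for row in self.cases.itertuples(index=False):
            pid = row.primaryid
            d = drugs_by.get(pid)
            drugs = (
                [
                    (r.DRUGNAME, getattr(r, "ROLE_COD", ""), None)
                    for r in d.itertuples(index=False)
                ]
                if d is not None
                else []
            )
            r = reac_by.get(pid)
            events = list(r["PT"]) if r is not None else []
            i = indi_by.get(pid)
            indis = list(i["INDI_PT"]) if i is not None else []
            yield CaseReport(
                caseid=row.caseid,
                primaryid=pid,
                sex=row.sex,
                age_years=None if pd.isna(row.age_years) else float(row.age_years),
                age_group=row.age_group,
                occupation=row.occupation,
                country=row.country,
                year=None if pd.isna(row.year) else int(row.year),
                outcomes=frozenset(() if pd.isna(row.outcome_codes) or not row.outcome_codes
                                   else row.outcome_codes.split("|")),
                drugs=drugs,
                events=events,
                indications=indis,
            )


def _group_by_pid(df: pd.DataFrame) -> dict:
    if len(df) == 0 or "PRIMARYID" not in df.columns:
        return {}
    return dict(tuple(df.groupby("PRIMARYID", sort=False)))


def normalize_age(age: object, age_cod: object) -> float:
    """AGE + AGE_COD → age in years; implausible (>120 y) or unparsable → NaN."""
    try:
        value = float(age)
    except (TypeError, ValueError):
        return np.nan
    if np.isnan(value) or value < 0:
        return np.nan
    code = str(age_cod).strip().upper() if age_cod is not None else "YR"
    if code in ("", "NAN", "NONE"):
        code = "YR"
    factor = AGE_UNIT_FACTORS.get(code)
    if factor is None:
        return np.nan
    years = value * factor
    return years if years <= MAX_PLAUSIBLE_AGE else np.nan


def age_group(age_years: float) -> str:
    """Bin an age in years into <18 / 18-64 / 65-79 / >=80 / missing."""
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "missing"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64"
    if age_years < 80:
        return "65-79"
    return ">=80"


def deduplicate(raw: RawTables) -> CaseSet:
    """Collapse repeated submissions to one report per case.

    FDA practice for spontaneous-report counting: for each ``caseid`` keep
    the most recent submission (latest ``FDA_DT``), breaking ties by the
    largest ``primaryid``.  Child-table rows of dropped primaryids are
    dropped with their parent.
    """
    demo = raw.demo
    if len(demo) == 0:
        raise ValueError("DEMO table is empty; nothing to deduplicate")
    demo = demo.copy()
    if "fda_dt_date" not in demo.columns:
        demo = _parse_date_column(demo, "FDA_DT")
    if "event_dt_date" not in demo.columns:
        if "EVENT_DT" not in demo.columns:
            demo["EVENT_DT"] = np.nan
        demo = _parse_date_column(demo, "EVENT_DT")
    # numeric primaryid sort key where possible
    pid_key = pd.to_numeric(demo["PRIMARYID"], errors="coerce")
    demo = demo.assign(_pid_key=pid_key.fillna(-1))
    demo = demo.sort_values(
        ["CASEID", "fda_dt_date", "_pid_key", "PRIMARYID"],
        kind="mergesort",
    )
    keep = demo.drop_duplicates("CASEID", keep="last")
    n_dropped = len(demo) - len(keep)
    if n_dropped:
        logger.info("deduplicate: removed %d duplicate report(s)", n_dropped)

    sex = keep.get("SEX", pd.Series(index=keep.index, dtype=object))
    sex = sex.where(sex.isin(["F", "M"]), "missing").fillna("missing")
    ages = [
        normalize_age(a, c)
        for a, c in zip(
            keep.get("AGE", pd.Series(index=keep.index, dtype=object)),
            keep.get("AGE_COD", pd.Series(index=keep.index, dtype=object)),
        )
    ]
    occ = (
        keep.get("OCCP_COD", pd.Series(index=keep.index, dtype=object))
        .map(lambda v: OCCUPATION_CODES.get(str(v).strip().upper(), "missing")
             if pd.notna(v) else "missing")
    )
    country = (
        keep.get("REPORTER_COUNTRY", pd.Series(index=keep.index, dtype=object))
        .fillna("missing")
    )
    year = keep["fda_dt_date"].dt.year

    keep_pid = set(keep["PRIMARYID"])
    outc = raw.outc
    if len(outc):
        outc = outc[outc["PRIMARYID"].isin(keep_pid)]
        per_case = (
            outc.groupby("PRIMARYID")["OUTC_COD"]
            .apply(lambda s: "|".join(sorted({str(v).strip().upper() for v in s if pd.notna(v)})))
        )
    else:
        per_case = pd.Series(dtype=object)

    cases = pd.DataFrame(
        {
            "caseid": keep["CASEID"].values,
            "primaryid": keep["PRIMARYID"].values,
            "sex": sex.values,
            "age_years": ages,
            "occupation": occ.values,
            "country": country.values,
            "year": year.values,
            "event_date": keep["event_dt_date"].values,
            "event_date_precision": keep["event_dt_precision"].values,
            "fda_date": keep["fda_dt_date"].values,
        }
    )
    cases["age_group"] = [age_group(a) for a in cases["age_years"]]
    cases["outcome_codes"] = cases["primaryid"].map(per_case).fillna("")

    def _sub(df: pd.DataFrame) -> pd.DataFrame:
        if len(df) == 0:
            return df
        return df[df["PRIMARYID"].isin(keep_pid)].reset_index(drop=True)

    return CaseSet(
        cases=cases.reset_index(drop=True),
        drugs=_sub(raw.drug),
        reactions=_sub(raw.reac),
        outcomes=_sub(raw.outc),
        therapies=_sub(raw.ther),
        indications=_sub(raw.indi),
        provenance=[f"deduplicated: {len(cases)} cases, {n_dropped} duplicates removed"],
    )


_NON_ALNUM = re.compile(r"[^a-z0-9]")


def _normalize_name(name: object) -> str:
    return _NON_ALNUM.sub("", str(name).lower())


def match_drug(
    cases: CaseSet,
    name_patterns: Sequence[Sequence[str]] | Sequence[str],
    roles: Sequence[str] = ("PS", "SS", "C", "I"),
) -> CaseSet:
    """Keep cases in which every required agent appears in an allowed role.

    ``name_patterns`` is a sequence of pattern groups, one group per required
    agent (e.g. ``[["durvalumab", "imfinzi"], ["tremelimumab", "imjudo"]]``);
    a flat list of strings is treated as a single group.  Matching is
    case-insensitive substring after stripping non-alphanumerics, against
    both DRUGNAME and PROD_AI.  Pass ``roles=("PS",)`` for the strict
    primary-suspect-only mode.
    """
    if not name_patterns:
        raise ValueError("name_patterns must be non-empty")
    if isinstance(name_patterns[0], str):
        groups: list[list[str]] = [list(name_patterns)]  # type: ignore[arg-type]
    else:
        groups = [list(g) for g in name_patterns]
    groups = [[_normalize_name(p) for p in g] for g in groups]
    roles_up = {r.upper() for r in roles}

    drug = cases.drugs
    if len(drug) == 0:
        logger.warning("match_drug: no drug records; empty result")
        return cases.restrict([], f"match_drug{groups!r}: empty drug table")

    ok_role = drug["ROLE_COD"].astype(str).str.upper().isin(roles_up)
    names = drug["DRUGNAME"].map(_normalize_name)
    if "PROD_AI" in drug.columns:
        ai = drug["PROD_AI"].map(_normalize_name)
    else:
        ai = pd.Series("", index=drug.index)

    pid_sets = []
    for g in groups:
        hit = pd.Series(False, index=drug.index)
        for pat in g:
            hit |= names.str.contains(pat, regex=False) | ai.str.contains(
                pat, regex=False
            )
        pid_sets.append(set(drug.loc[hit & ok_role, "PRIMARYID"]))
    keep_pid = set.intersection(*pid_sets) if pid_sets else set()
    keep_case = cases.cases.loc[
        cases.cases["primaryid"].isin(keep_pid), "caseid"
    ]
    if len(keep_case) == 0:
        logger.warning("match_drug: no case matched all agent groups")
    return cases.restrict(
        keep_case, f"match_drug(roles={sorted(roles_up)}): {len(keep_case)} cases"
    )


def filter_indication(cases: CaseSet, term: str) -> CaseSet:
    """Keep cases with at least one indication containing ``term`` (case-insensitive)."""
    if not term:
        raise ValueError("indication term must be non-empty")
    indi = cases.indications
    if len(indi) == 0:
        return cases.restrict([], f"filter_indication({term!r}): empty INDI table")
    hit = indi["INDI_PT"].astype(str).str.lower().str.contains(term.lower(), regex=False)
    keep_pid = set(indi.loc[hit, "PRIMARYID"])
    keep_case = cases.cases.loc[cases.cases["primaryid"].isin(keep_pid), "caseid"]
    return cases.restrict(keep_case, f"filter_indication({term!r}): {len(keep_case)} cases")


# ---------------------------------------------------------------------------
# demographics


@dataclass
class DemographicsTable:
    """Counts and percentages per demographic block, denominator = all reports."""

    table: pd.DataFrame  # columns: block, category, n, percent
    n_reports: int
    total_serious: int

    @property
    def total_serious_percent(self) -> float:
        if self.n_reports == 0:
            return float("nan")
        return round(100.0 * self.total_serious / self.n_reports, 1)


def summarize_demographics(cases: CaseSet, top_countries: int = 5) -> DemographicsTable:
    """Tabulate sex, age group, reporter occupation, serious outcomes,
    country (top-k + "Other countries") and reporting year.

    A report contributes once to each distinct serious-outcome category it
    carries; the serious roll-up is the sum over the five serious categories.
    """
    df = cases.cases
    n = len(df)
    rows: list[tuple[str, str, int]] = []

    def _block(name: str, series: pd.Series, order: Sequence[str]) -> None:
        counts = series.value_counts()
        for cat in order:
            rows.append((name, cat, int(counts.get(cat, 0))))

    sex = df["sex"].replace({"F": "Female", "M": "Male"}) if n else pd.Series(dtype=object)
    _block("Sex", sex.replace({"missing": "Missing"}), ["Female", "Male", "Missing"])
    _block(
        "Age",
        df["age_group"].replace({"missing": "Missing"}) if n else pd.Series(dtype=object),
        list(AGE_BINS) + ["Missing"],
    )
    occ = (
        df["occupation"].replace({"missing": "Missing"}).str.capitalize().replace(
            {"Health-professional": "Health-professional"}
        )
        if n
        else pd.Series(dtype=object)
    )
    _block("Occupation reporter", occ,
           ["Physician", "Pharmacist", "Health-professional", "Consumer", "Missing"])

    # serious outcomes: once per distinct category per report
    cat_counts = {c: 0 for c in SERIOUS_CATEGORY_ORDER}
    n_no_outcome = 0
    if n:
        for codes in df["outcome_codes"]:
            cats = {
                OUTCOME_CATEGORIES[c]
                for c in (codes.split("|") if codes else [])
                if c in OUTCOME_CATEGORIES
            }
            if not cats:
                n_no_outcome += 1
            for c in cats:
                cat_counts[c] += 1
    for c in SERIOUS_CATEGORY_ORDER:
        rows.append(("Serious outcome", c, cat_counts[c]))
    rows.append(("Serious outcome", "Missing", n_no_outcome))
    total_serious = sum(cat_counts.values())

    if n:
        country = df["country"].replace({"missing": "Missing"})
        top = country.value_counts()
        top = top[top.index != "Missing"].head(top_countries)
        for c, k in top.items():
            rows.append(("Reporting country", str(c), int(k)))
        rows.append(("Reporting country", "Other countries", int(n - top.sum())))
    else:
        rows.append(("Reporting country", "Other countries", 0))

    if n:
        years = df["year"].dropna().astype(int)
        for y in sorted(years.unique()):
            rows.append(("Reporting year", str(y), int((years == y).sum())))
        n_missing_year = int(df["year"].isna().sum())
        if n_missing_year:
            rows.append(("Reporting year", "Missing", n_missing_year))

    out = pd.DataFrame(rows, columns=["block", "category", "n"])
    out["percent"] = (
        (100.0 * out["n"] / n).round(1) if n else np.nan
    )
    return DemographicsTable(table=out, n_reports=n, total_serious=total_serious)
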