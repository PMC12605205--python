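"""Time-to-onset (TTO) analysis: interval summaries, Kaplan-Meier curves
with log-rank tests, and Weibull hazard-shape classification.

TTO is the number of days from therapy start (earliest START_DT among the
suspect drugs' therapy rows) to adverse-event onset (the report's EVENT_DT).
Records with a missing date, an event before the start, or sub-day precision
are excluded.  The Weibull shape β classifies the hazard trajectory:
decreasing (early failure, CI entirely below 1), constant (random failure,
CI covering 1) or increasing (wear-out failure, CI entirely above 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, WeibullFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .ingest import CaseSet

logger = logging.getLogger(__name__)

TTO_BIN_EDGES = (0, 30, 60, 90, 180, 365)
TTO_BIN_LABELS = ("0-29", "30-59", "60-89", "90-179", "180-364", ">=365")

EARLY_FAILURE = "early_failure"
RANDOM_FAILURE = "random_failure"
WEAR_OUT_FAILURE = "wear_out_failure"


def _match_mask(series: pd.Series, patterns: list[str]) -> pd.Series:
    s = series.astype(str).str.upper().str.replace(r"[^A-Z0-9]", "", regex=True)
    mask = pd.Series(False, index=series.index)
    for p in patterns:
        mask |= s.str.contains(p.upper(), regex=False)
    return mask


def compute_tto(cases: CaseSet,
                drug_patterns: list[str] | None = None,
                allow_month_precision: bool = False) -> pd.DataFrame:
    """Build one TTO record per (case, PT).

    The start date is the earliest START_DT over the THER rows of the
    suspect drugs (all THER rows when ``drug_patterns`` is None); the event
    date is the report-level EVENT_DT, so all PTs of a case share its
    interval.  Cases with missing dates, EVENT_DT < START_DT, or less than
    day precision (unless ``allow_month_precision``) are excluded and the
    exclusions logged.

    Returns a frame with caseid, pt, tto_days, sex, age_group, fatal.
    """
    ther = cases.therapies
    if len(ther) == 0 or "START_DT" not in ther.columns:
        logger.warning("compute_tto: no therapy records; 0 usable records")
        return pd.DataFrame(
            columns=["caseid", "pt", "tto_days", "sex", "age_group", "fatal"])
    ther = ther.copy()
    if "start_dt_date" not in ther.columns:
        from .ingest import parse_faers_date
        parsed = [parse_faers_date(v) for v in ther["START_DT"]]
        ther["start_dt_date"] = [p[0] for p in parsed]
        ther["start_dt_precision"] = [p[1] for p in parsed]

    if drug_patterns:
        drugs = cases.drugs
        seq_col = "DRUG_SEQ" if "DRUG_SEQ" in drugs.columns else None
        tseq_col = "DSG_DRUG_SEQ" if "DSG_DRUG_SEQ" in ther.columns else None
        hit = _match_mask(drugs["DRUGNAME"], drug_patterns)
        if "PROD_AI" in drugs.columns:
            hit |= _match_mask(drugs["PROD_AI"].fillna(""), drug_patterns)
        if seq_col and tseq_col:
            key = drugs.loc[hit, ["PRIMARYID", seq_col]].rename(
                columns={seq_col: "seq"})
            ther = ther.merge(
                key.drop_duplicates(),
                left_on=["PRIMARYID", tseq_col],
                right_on=["PRIMARYID", "seq"],
            )
        else:
            ther = ther[ther["PRIMARYID"].isin(set(drugs.loc[hit, "PRIMARYID"]))]

    ok_prec = ("day", "month") if allow_month_precision else ("day",)
    ther = ther[ther["start_dt_precision"].isin(ok_prec)]
    start = ther.groupby("PRIMARYID")["start_dt_date"].min()

    cc = cases.cases
    df = cc.assign(start_date=cc["primaryid"].map(start))
    n0 = len(df)
    event_ok = df["event_date_precision"].isin(ok_prec)
    usable = df["start_date"].notna() & df["event_date"].notna() & event_ok
    df = df[usable].copy()
    df["tto_days"] = (df["event_date"] - df["start_date"]).dt.days
    n_negative = int((df["tto_days"] < 0).sum())
    df = df[df["tto_days"] >= 0]
    logger.info(
        "compute_tto: %d of %d cases usable (%d missing/imprecise, %d negative)",
        len(df), n0, int((~usable).sum()), n_negative)

    fatal = df["outcome_codes"].str.split("|").map(lambda v: "DE" in v)
    base = pd.DataFrame({
        "caseid": df["caseid"],
        "tto_days": df["tto_days"].astype(int),
        "sex": df["sex"],
        "age_group": df["age_group"],
        "fatal": fatal,
    })
    reac = cases.reactions
    pts = pd.DataFrame({"caseid": reac["CASEID"],
                        "pt": reac["PT"].astype(str)}).drop_duplicates()
    out = base.merge(pts, on="caseid", how="inner")
    return out[["caseid", "pt", "tto_days", "sex", "age_group", "fatal"]]


# ---------------------------------------------------------------------------


def median_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI for the median from binomial order statistics."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    if n < 2:
        return (math.nan, math.nan)
    lo_rank = stats.binom.ppf((1 - level) / 2, n, 0.5)
    hi_rank = stats.binom.ppf(1 - (1 - level) / 2, n, 0.5)
    lo = x[int(max(lo_rank - 1, 0))]
    hi = x[int(min(hi_rank, n - 1))]
    return (float(lo), float(hi))


def tto_summary(tto_days: np.ndarray | pd.Series) -> dict:
    """Median (with order-statistic 95% CI), IQR, range and interval bins.

    Bins are half-open: [0,30), [30,60), [60,90), [90,180), [180,365),
    [365, ∞); shares use the record count as denominator.
    """
    x = np.asarray(tto_days, float)
    if len(x) == 0:
        raise ValueError("no TTO records")
    edges = list(TTO_BIN_EDGES) + [np.inf]
    counts, _ = np.histogram(x, bins=edges)
    bins = pd.DataFrame({
        "bin": TTO_BIN_LABELS,
        "n": counts.astype(int),
        "share_percent": np.round(100.0 * counts / len(x), 2),
    })
    q1, q3 = np.percentile(x, [25, 75])
    lo, hi = median_ci(x)
    return {
        "n": len(x),
        "median": float(np.median(x)),
        "median_ci": (lo, hi),
        "iqr": (float(q1), float(q3)),
        "min": float(x.min()),
        "max": float(x.max()),
        "bins": bins,
    }


def km_curve(records: pd.DataFrame, strata: str | None = None,
             time_col: str = "tto_days") -> dict:
    """Kaplan-Meier onset curves (all events observed) plus a log-rank test
    across strata.

    Returns ``{"curves": DataFrame(time, estimate, n_risk, stratum),
    "logrank_chi2": float | None, "logrank_p": float | None}``; a single
    stratum gives a curve only.
    """
    if strata is None:
        groups = {"all": records}
    else:
        groups = {str(k): g for k, g in records.groupby(strata)}
    curves = []
    for name, g in groups.items():
        if len(g) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(g[time_col], event_observed=np.ones(len(g)))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "estimate"]
        at_risk = kmf.event_table["at_risk"].reindex(sf["time"]).to_numpy()
        sf["n_risk"] = at_risk
        sf["stratum"] = name
        curves.append(sf)
    out = {"curves": pd.concat(curves, ignore_index=True),
           "logrank_chi2": None, "logrank_p": None}
    usable = {k: g for k, g in groups.items() if len(g) >= 2}
    if strata is not None and len(usable) >= 2:
        stacked = pd.concat(
            [g.assign(_g=k) for k, g in usable.items()], ignore_index=True)
        res = multivariate_logrank_test(
            stacked[time_col], stacked["_g"], np.ones(len(stacked)))
        out["logrank_chi2"] = float(res.test_statistic)
        out["logrank_p"] = float(res.p_value)
    return out


# ---------------------------------------------------------------------------
# Weibull


@dataclass
class WeibullFit:
    """Weibull MLE of onset times with delta-method CIs and hazard category."""

    shape: float
    shape_ci: tuple[float, float]
    scale: float
    scale_ci: tuple[float, float]
    n: int
    loglik: float

    @property
    def category(self) -> str:
        return classify_failure(self.shape, *self.shape_ci)


def weibull_fit(tto_days: np.ndarray | pd.Series, min_n: int = 10) -> WeibullFit:
    """Maximum-likelihood Weibull fit of onset times.

    Zero-day onsets are shifted by +0.5 day (the likelihood needs t > 0);
    95% CIs come from the observed information on the log scale,
    back-transformed.  Requires at least ``min_n`` records.
    """
    x = np.asarray(tto_days, float)
    if len(x) < min_n:
        raise ValueError(f"need ≥ {min_n} records for a Weibull fit, got {len(x)}")
    if (x < 0).any():
        raise ValueError("negative onset times")
    x = np.where(x == 0, 0.5, x)
    wf = WeibullFitter()
    wf.fit(x, event_observed=np.ones(len(x)))
    summ = wf.summary
    shape = float(wf.rho_)
    scale = float(wf.lambda_)
    s_lo = float(summ.loc["rho_", "coef lower 95%"])
    s_hi = float(summ.loc["rho_", "coef upper 95%"])
    l_lo = float(summ.loc["lambda_", "coef lower 95%"])
    l_hi = float(summ.loc["lambda_", "coef upper 95%"])
    return WeibullFit(
        shape=shape, shape_ci=(s_lo, s_hi),
        scale=scale, scale_ci=(l_lo, l_hi),
        n=len(x), loglik=float(wf.log_likelihood_),
    )


def classify_failure(shape: float, lo: float, hi: float) -> str:
    """Hazard-trajectory category from the Weibull shape and its 95% CI.

    early failure: β < 1 with CI upper bound < 1 (decreasing risk);
    random failure: CI covers 1 (constant risk);
    wear-out failure: β > 1 with CI lower bound > 1 (increasing risk).
    The three cases are exhaustive and mutually exclusive when lo ≤ hi.
    """
    if not (lo <= shape <= hi):
        raise ValueError(f"inconsistent CI: {lo} ≤ {shape} ≤ {hi} fails")
    if hi < 1.0:
        return EARLY_FAILURE
    if lo > 1.0:
        return WEAR_OUT_FAILURE
    return RANDOM_FAILURE


def fit_per_pt(records: pd.DataFrame, pts: list[str] | None = None,
               min_n: int = 10) -> pd.DataFrame:
    """Weibull fit + category per PT; PTs under ``min_n`` records are
    reported as insufficient rather than fitted."""
    rows = []
    wanted = pts if pts is not None else sorted(records["pt"].unique())
    for pt in wanted:
        x = records.loc[records["pt"] == pt, "tto_days"].to_numpy()
        if len(x) < min_n:
            rows.append({"pt": pt, "n": len(x), "status": "insufficient"})
            continue
        try:
            fit = weibull_fit(x, min_n=min_n)
        except Exception as exc:  # non-convergence
            rows.append({"pt": pt, "n": len(x), "status": f"failed: {exc}"})
            continue
        rows.append({
            "pt": pt, "n": fit.n, "status": "ok",
            "shape": fit.shape, "shape_lo": fit.shape_ci[0],
            "shape_hi": fit.shape_ci[1],
            "scale": fit.scale, "scale_lo": fit.scale_ci[0],
            "scale_hi": fit.scale_ci[1],
            "category": fit.category,
        })
    return pd.DataFrame(rows)
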