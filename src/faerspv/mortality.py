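"""Drug-related-mortality risk modelling: LASSO-Cox variable selection,
multivariable Cox fit, linear risk score, median-split stratification and
time-dependent ROC evaluation.

The survival record per case runs from therapy start (START_DT) to the fatal
adverse event date (EVENT_DT, OUTC_COD ``DE``) or to administrative
censoring at the last recorded event date.  Candidate covariates are sex,
age and indicator columns for consensus-positive preferred terms occurring
in at least ``min_pt_cases`` cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .ingest import CaseSet
from .tto import compute_tto

logger = logging.getLogger(__name__)

DEFAULT_HORIZONS = (30.0, 60.0, 90.0)


def build_design_matrix(cases: CaseSet, positive_pts: list[str],
                        drug_patterns: list[str] | None = None,
                        min_pt_cases: int = 2,
                        min_records: int = 20,
                        censor_days: float | None = None) -> pd.DataFrame:
    """One survival record per case with complete sex, age and dates.

    ``time_days`` is EVENT_DT − START_DT (the fatal AE onset for deaths);
    non-fatal cases are censored at their last recorded event date — all a
    spontaneous-report database knows — unless ``censor_days`` imposes a
    known administrative follow-up window (as in simulated data, where the
    generator's fatal-outcome process runs over a fixed window).  ``event``
    is 1 when OUTC_COD contains ``DE``.  Candidate PT columns are the
    consensus-positive PTs present in at least ``min_pt_cases`` of the
    usable cases; sex is coded male=1.
    """
    tto = compute_tto(cases, drug_patterns=drug_patterns)
    if len(tto) == 0:
        raise ValueError("no usable records with complete dates")
    per_case = tto.drop_duplicates("caseid").set_index("caseid")
    cc = cases.cases.set_index("caseid")
    base = per_case.join(cc[["age_years"]], how="left")
    base = base[base["sex"].isin(["F", "M"]) & base["age_years"].notna()]
    n_dropped = len(per_case) - len(base)
    if n_dropped:
        logger.info("build_design_matrix: dropped %d case(s) with missing "
                    "sex/age", n_dropped)

    time_days = base["tto_days"].astype(float).clip(lower=0.5)
    if censor_days is not None:
        time_days = time_days.where(base["fatal"], float(censor_days))
    df = pd.DataFrame({
        "time_days": time_days,
        "event": base["fatal"].astype(int),
        "male": (base["sex"] == "M").astype(int),
        "age_years": base["age_years"].astype(float),
    })
    pt_pairs = tto[tto["caseid"].isin(base.index)]
    kept_pts = []
    for pt in positive_pts:
        hit = set(pt_pairs.loc[pt_pairs["pt"] == pt, "caseid"])
        if len(hit) < min_pt_cases:
            logger.info("build_design_matrix: PT %r below the %d-case floor, "
                        "dropped", pt, min_pt_cases)
            continue
        col = "pt_" + pt.lower().replace(" ", "_").replace("-", "_")
        df[col] = df.index.isin(hit).astype(int)
        kept_pts.append(pt)
    df.attrs["pt_columns"] = {
        "pt_" + pt.lower().replace(" ", "_").replace("-", "_"): pt
        for pt in kept_pts}
    if len(df) < min_records:
        raise ValueError(
            f"only {len(df)} usable records; the model is not identifiable")
    return df


# ---------------------------------------------------------------------------
# partial likelihood (Breslow) — used for cross-validated deviance


def breslow_loglik(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                   beta: np.ndarray) -> float:
    """Breslow partial log-likelihood at ``beta``."""
    eta = x @ beta
    order = np.argsort(-time, kind="mergesort")
    eta = eta[order]
    t = time[order]
    ev = event[order].astype(bool)
    # cumulative log-sum-exp over the risk set (descending time)
    m = eta.max()
    csum = np.cumsum(np.exp(eta - m))
    # risk set of an event at t_i: all with time >= t_i → handle ties by
    # taking the last index with equal time
    ll = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        log_denominator = m + np.log(csum[j])
        for k in range(i, j + 1):
            if ev[k]:
                ll += eta[k] - log_denominator
        i = j + 1
    return float(ll)


@dataclass
class LassoPath:
    """L1-penalised Cox path with cross-validated deviance."""

    alphas: np.ndarray
    coefs: pd.DataFrame  # variables × alphas
    cv_deviance: np.ndarray
    alpha_min: float
    selected: list[str]
    seed: int | None = None


def lasso_cox_select(records: pd.DataFrame, folds: int = 10,
                     seed: int | None = None, n_alphas: int = 50,
                     standardize: bool = True,
                     alphas: np.ndarray | None = None) -> LassoPath:
    """Select covariates by L1-penalised Cox regression.

    The penalty weight λ runs over a log-spaced grid; k-fold cross-validated
    partial-likelihood deviance (Verweij–van Houwelingen form) picks λ*, and
    the selected set is the nonzero coefficients at λ*.
    """
    covars = [c for c in records.columns if c not in ("time_days", "event")]
    x = records[covars].to_numpy(float)
    if standardize:
        mu, sd = x.mean(0), x.std(0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    time = records["time_days"].to_numpy(float)
    event = records["event"].to_numpy(int)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    n_events = int(event.sum())
    if n_events < 2 * folds:
        logger.warning("lasso_cox_select: only %d events for %d folds",
                       n_events, folds)

    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                   alpha_min_ratio=1e-3, max_iter=100000)
    if alphas is not None:
        model.set_params(alphas=list(np.sort(alphas)[::-1]))
    model.fit(x, y)
    grid = np.asarray(model.alphas_)

    kf = KFold(n_splits=folds, shuffle=True,
               random_state=None if seed is None else seed)
    dev = np.zeros(len(grid))
    for train, _test in kf.split(x):
        fold_model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=list(grid), max_iter=100000)
        fold_model.fit(x[train], y[train])
        # the solver may stop the path early; map each grid alpha to the
        # nearest alpha it actually computed
        fold_alphas = np.log(np.asarray(fold_model.alphas_))
        for j, alpha in enumerate(grid):
            col = int(np.argmin(np.abs(fold_alphas - np.log(alpha))))
            beta = fold_model.coef_[:, col]
            ll_full = breslow_loglik(x, time, event, beta)
            ll_train = breslow_loglik(x[train], time[train], event[train], beta)
            dev[j] += -2.0 * (ll_full - ll_train)

    j_min = int(np.argmin(dev))
    alpha_min = float(grid[j_min])
    beta_min = model.coef_[:, j_min]
    selected = [c for c, b in zip(covars, beta_min) if b != 0.0]
    if not selected:
        logger.warning("lasso_cox_select: empty selection at λ*; downstream "
                       "Cox fit will be skipped")
    coefs = pd.DataFrame(model.coef_, index=covars, columns=grid)
    return LassoPath(alphas=grid, coefs=coefs, cv_deviance=dev,
                     alpha_min=alpha_min, selected=selected, seed=seed)


def cox_fit(records: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Multivariable Cox PH fit (Efron ties) of the selected variables.

    Returns a frame indexed by variable with coef, HR, 95% CI, p and an
    ``independent`` flag (Wald p < 0.05).
    """
    if not variables:
        raise ValueError("no variables to fit")
    n_events = int(records["event"].sum())
    if n_events < 10 * len(variables):
        logger.warning("cox_fit: %d events for %d variables (< 10 per "
                       "variable)", n_events, len(variables))
    cph = CoxPHFitter()
    try:
        cph.fit(records[["time_days", "event"] + variables],
                duration_col="time_days", event_col="event")
    except Exception as exc:
        raise RuntimeError(f"Cox fit failed ({exc}); check the candidate "
                           "variables for separation") from exc
    s = cph.summary
    out = pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "hr_lo": s["exp(coef) lower 95%"],
        "hr_hi": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    out["independent"] = out["p"] < 0.05
    return out


def risk_score(indicators: pd.DataFrame | pd.Series | dict,
               coefficients: dict[str, float] | pd.Series) -> np.ndarray | float:
    """Linear predictor Σ βᵢ·xᵢ over the final-model variables only.

    ``indicators`` must provide a value for every coefficient variable;
    unknown variables in a record are an error.
    """
    coefs = pd.Series(coefficients, dtype=float)
    if isinstance(indicators, dict):
        indicators = pd.Series(indicators, dtype=float)
    if isinstance(indicators, pd.Series):
        unknown = set(indicators.index) - set(coefs.index)
        if unknown:
            raise ValueError(f"unknown variable(s) in record: {sorted(unknown)}")
        return float(sum(coefs[k] * indicators.get(k, 0.0)
                         for k in coefs.index if k in indicators.index))
    missing = [k for k in coefs.index if k not in indicators.columns]
    if missing:
        raise ValueError(f"records lack model variable(s): {missing}")
    return indicators[list(coefs.index)].to_numpy(float) @ coefs.to_numpy()


@dataclass
class StratificationResult:
    group: pd.Series  # "high" / "low" per record
    median_cutoff: float
    logrank_p: float | None
    logrank_chi2: float | None
    km_curves: pd.DataFrame


def stratify_and_test(scores: np.ndarray, records: pd.DataFrame
                      ) -> StratificationResult:
    """Median split of the risk score (ties to low) with per-group KM curves
    and a log-rank test."""
    scores = np.asarray(scores, float)
    if len(scores) < 4:
        raise ValueError("need at least 4 records to stratify")
    cutoff = float(np.median(scores))
    group = pd.Series(np.where(scores > cutoff, "high", "low"),
                      index=records.index)
    curves = []
    for name in ("high", "low"):
        mask = group == name
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(records.loc[mask, "time_days"], records.loc[mask, "event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "estimate"]
        sf["stratum"] = name
        curves.append(sf)
    km = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()
    if group.nunique() < 2:
        logger.warning("stratify_and_test: degenerate scores, single group")
        return StratificationResult(group, cutoff, None, None, km)
    hi, lo = group == "high", group == "low"
    res = logrank_test(records.loc[hi, "time_days"], records.loc[lo, "time_days"],
                       records.loc[hi, "event"], records.loc[lo, "event"])
    return StratificationResult(group, cutoff, float(res.p_value),
                                float(res.test_statistic), km)


def time_dependent_roc(scores: np.ndarray, records: pd.DataFrame,
                       horizons: tuple[float, ...] = DEFAULT_HORIZONS
                       ) -> pd.DataFrame:
    """Cumulative-case / dynamic-control AUC(t) with IPCW at each horizon.

    Horizons with no prior event (or beyond the follow-up range) come back
    with a NaN AUC and a reason flag.
    """
    scores = np.asarray(scores, float)
    time = records["time_days"].to_numpy(float)
    event = records["event"].to_numpy(bool)
    y = Surv.from_arrays(event=event, time=time)
    rows = []
    t_max = time[~event].max() if (~event).any() else time.max()
    for h in horizons:
        if not (event & (time <= h)).any():
            rows.append({"horizon": h, "auc": np.nan, "flag": "no events"})
            continue
        if h >= t_max:
            rows.append({"horizon": h, "auc": np.nan,
                         "flag": "beyond follow-up"})
            continue
        auc, _mean = cumulative_dynamic_auc(y, y, scores, [h])
        rows.append({"horizon": h, "auc": float(auc[0]), "flag": ""})
    return pd.DataFrame(rows)


@dataclass
class RiskModelFit:
    """Everything the mortality-risk stage produces."""

    lasso: LassoPath
    cox: pd.DataFrame | None
    coefficients: dict[str, float]
    scores: np.ndarray | None
    stratification: StratificationResult | None
    roc: pd.DataFrame | None
    n_records: int
    n_events: int


def fit_risk_model(records: pd.DataFrame, folds: int = 10,
                   seed: int | None = None,
                   horizons: tuple[float, ...] = DEFAULT_HORIZONS
                   ) -> RiskModelFit:
    """LASSO selection → Cox fit → risk score → median split → AUC(t)."""
    path = lasso_cox_select(records, folds=folds, seed=seed)
    n_events = int(records["event"].sum())
    if not path.selected:
        return RiskModelFit(path, None, {}, None, None, None,
                            len(records), n_events)
    cox = cox_fit(records, path.selected)
    coefs = cox["coef"].to_dict()
    scores = risk_score(records, coefs)
    strat = stratify_and_test(scores, records)
    roc = time_dependent_roc(scores, records, horizons)
    return RiskModelFit(path, cox, coefs, scores, strat, roc,
                        len(records), n_events)
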