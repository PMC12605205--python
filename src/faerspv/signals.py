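"""Disproportionality analysis: ROR, PRR, BCPNN information component and
the DuMouchel multi-item gamma Poisson shrinker, with consensus signal calls.

All four statistics work on the same report-level 2×2 contingency table for a
drug–event pair within a report universe::

                      target PT     other PTs
    target drug           a             b
    other drugs           c             d

with ``N = a+b+c+d`` and expected count ``E = (a+b)(a+c)/N`` under
independence.  A report contributes at most once to each cell regardless of
how many times the PT occurs on it.

A preferred term is called a *consensus signal* only when all four
algorithms exceed their (configurable) published thresholds:
ROR — a ≥ 3 and lower 95% CI > 1; PRR — a ≥ 3, PRR ≥ 2, Yates χ² ≥ 4;
BCPNN — IC025 > 0; MGPS — EBGM05 ≥ 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace  # noqa: F401
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .ingest import CaseSet

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one drug–event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a under row/column independence, (a+b)(a+c)/N."""
        if self.n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass
class SignalThresholds:
    """Per-algorithm positivity criteria (published defaults)."""

    min_cases: int = 3
    ror_lo: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


@dataclass
class PriorParams:
    """DuMouchel two-component gamma mixture prior for the MGPS."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = float("nan")
    converged: bool = True

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.alpha1, self.beta1, self.alpha2, self.beta2, self.w)


CANONICAL_START = PriorParams(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0,
                              w=1.0 / 3.0)


def build_contingency(cohort: CaseSet, universe: CaseSet, pt: str) -> ContingencyTable:
    """Count reports for ``pt`` inside/outside the cohort within the universe."""
    cohort_ids = set(cohort.caseids)
    universe_ids = set(universe.caseids)
    if not cohort_ids <= universe_ids:
        raise ValueError("cohort is not a subset of the universe")
    pt_lower = pt.lower()
    with_pt = {
        cid
        for cid, p in zip(universe.reactions["CASEID"], universe.reactions["PT"])
        if str(p).lower() == pt_lower
    }
    a = len(with_pt & cohort_ids)
    c = len(with_pt & universe_ids) - a
    b = len(cohort_ids) - a
    d = len(universe_ids) - len(cohort_ids) - c
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# frequentist statistics


def ror_stats(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio ad/bc with lognormal 95% CI.

    Any zero cell makes the estimate undefined (NaN) unless the
    Haldane–Anscombe correction applies upstream; callers treat NaN as
    "no signal".
    """
    a, b, c, d = _continuity_cells(t)
    if min(a, b, c, d) <= 0:
        return (math.nan, math.nan, math.nan)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


def prr_stats(t: ContingencyTable) -> tuple[float, float, float, float]:
    """Proportional reporting ratio, its lognormal 95% CI and Yates χ².

    PRR = [a/(a+b)] / [c/(c+d)].  χ² is the continuity-corrected 2×2
    statistic N(|ad−bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)].
    """
    a, b, c, d = _continuity_cells(t)
    n = a + b + c + d
    chi2 = math.nan
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom > 0:
        chi2 = n * max(0.0, abs(a * d - b * c) - n / 2) ** 2 / denom
    if a <= 0 or c <= 0 or a + b <= 0 or c + d <= 0:
        return (math.nan, math.nan, math.nan, chi2)
    prr = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    if var < 0:
        return (prr, math.nan, math.nan, chi2)
    se = math.sqrt(var)
    return (prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se), chi2)


def _continuity_cells(t: ContingencyTable) -> tuple[float, float, float, float]:
    """Haldane–Anscombe +0.5 on all cells, applied only when a ≥ 1 and
    exactly one of b, c, d is zero.  With a = 0 the pair is "no signal" by
    definition and the zero is left in place (the statistic comes out NaN)."""
    if t.a >= 1 and sum(1 for v in (t.b, t.c, t.d) if v == 0) == 1:
        return (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
    return (float(t.a), float(t.b), float(t.c), float(t.d))


def chi2_pvalue(t: ContingencyTable) -> float:
    """p-value for the 2×2 association: Yates χ², or Fisher's exact test
    whenever any expected cell count is below 5."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    if n == 0:
        return math.nan
    row = np.array([a + b, c + d], float)
    col = np.array([a + c, b + d], float)
    expected = np.outer(row, col) / n
    if (expected < 5).any():
        return float(stats.fisher_exact([[a, b], [c, d]])[1])
    denom = row.prod() * col.prod()
    chi2 = n * max(0.0, abs(a * d - b * c) - n / 2) ** 2 / denom
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# BCPNN information component


def bcpnn_ic(t: ContingencyTable, method: str = "noren") -> tuple[float, float]:
    """Information component IC = log2[(a+0.5)/(E+0.5)] and its 2.5% bound.

    ``method="noren"`` takes the exact 2.5% quantile of the shrinkage gamma
    posterior Ga(a+0.5, rate E+0.5) on the observed/expected ratio;
    ``method="approx"`` uses the closed-form
    IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2).
    """
    if t.n <= 0:
        raise ValueError("empty table")
    e = t.expected
    a_s = t.a + 0.5
    e_s = e + 0.5
    ic = math.log2(a_s / e_s)
    if method == "noren":
        q = stats.gamma.ppf(0.025, a_s, scale=1.0 / e_s)
        ic025 = math.log2(q) if q > 0 else -math.inf
    elif method == "approx":
        ic025 = ic - 3.3 * a_s ** -0.5 - 2.0 * a_s ** -1.5
    else:
        raise ValueError(f"unknown IC interval method {method!r}")
    return (ic, ic025)


# ---------------------------------------------------------------------------
# MGPS (DuMouchel empirical Bayes)


def _mixture_loglik(params: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    a1, b1, a2, b2, w = params
    # marginal of a | E is negative binomial with size α, p = β/(β+E)
    with np.errstate(invalid="ignore", divide="ignore"):
        l1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
        l2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
        ll = np.logaddexp(np.log(w) + l1, np.log1p(-w) + l2)
    if not np.isfinite(ll).all():
        return -1e300
    return float(ll.sum())


def mgps_fit(tables: Iterable[ContingencyTable] | tuple[np.ndarray, np.ndarray],
             start: PriorParams = CANONICAL_START) -> PriorParams:
    """Fit the two-gamma mixture prior by marginal maximum likelihood.

    ``tables`` is either a collection of contingency tables (one per
    drug–event pair of the universe) or a pre-computed ``(a, E)`` array pair.
    Bounded L-BFGS-B from the canonical start, with jittered multi-starts on
    non-convergence.
    """
    if isinstance(tables, tuple):
        a, e = (np.asarray(x, float) for x in tables)
    else:
        tables = list(tables)
        a = np.array([t.a for t in tables], float)
        e = np.array([t.expected for t in tables], float)
    if len(a) < 50:
        logger.warning("mgps_fit: only %d drug–event pairs; prior may be unstable",
                       len(a))
    e = np.maximum(e, 1e-10)

    bounds = [(1e-4, 50.0), (1e-4, 50.0), (1e-4, 50.0), (1e-4, 50.0),
              (1e-6, 1 - 1e-6)]

    def neg(params: np.ndarray) -> float:
        return -_mixture_loglik(params, a, e)

    starts = [np.array(start.as_tuple())]
    rng = np.random.default_rng(0)
    for _ in range(4):
        jitter = np.exp(rng.normal(0, 0.5, size=4))
        starts.append(np.array([0.2 * jitter[0], 0.1 * jitter[1],
                                2.0 * jitter[2], 4.0 * jitter[3],
                                rng.uniform(0.1, 0.9)]))
    best = None
    for x0 in starts:
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            if best is res or best.fun >= res.fun:
                best = res
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("MGPS prior fit failed from every start")
    a1, b1, a2, b2, w = best.x
    prior = PriorParams(a1, b1, a2, b2, w, loglik=-best.fun,
                        converged=bool(best.success))
    if not best.success:
        raise RuntimeError(
            f"MGPS prior fit did not converge; best-so-far {prior}"
        )
    return prior


def _posterior_weights(a: float, e: float, prior: PriorParams) -> tuple[float, float]:
    lw1 = math.log(prior.w) + stats.nbinom.logpmf(
        a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    lw2 = math.log1p(-prior.w) + stats.nbinom.logpmf(
        a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    m = max(lw1, lw2)
    q1 = math.exp(lw1 - m)
    q2 = math.exp(lw2 - m)
    return (q1 / (q1 + q2), q2 / (q1 + q2))


def ebgm_stats(t: ContingencyTable, prior: PriorParams) -> tuple[float, float]:
    """Posterior geometric mean EBGM = 2^E[log2 λ | a, E] and 5th percentile.

    The posterior on the relative reporting rate λ is the prior mixture
    updated to Ga(α_j+a, rate β_j+E) with data-dependent weights; the mean of
    log2 λ has the digamma closed form, and EBGM05 is found by root-finding
    on the mixture CDF.
    """
    a, e = t.a, max(t.expected, 1e-10)
    q1, q2 = _posterior_weights(a, e, prior)
    g1 = (prior.alpha1 + a, prior.beta1 + e)
    g2 = (prior.alpha2 + a, prior.beta2 + e)
    elog = q1 * (special.digamma(g1[0]) - math.log(g1[1])) + q2 * (
        special.digamma(g2[0]) - math.log(g2[1]))
    ebgm = 2.0 ** (elog / math.log(2.0))

    def cdf(x: float) -> float:
        return q1 * stats.gamma.cdf(x, g1[0], scale=1 / g1[1]) + q2 * stats.gamma.cdf(
            x, g2[0], scale=1 / g2[1])

    lo = min(stats.gamma.ppf(0.01, g1[0], scale=1 / g1[1]),
             stats.gamma.ppf(0.01, g2[0], scale=1 / g2[1]))
    hi = max(stats.gamma.ppf(0.4, g1[0], scale=1 / g1[1]),
             stats.gamma.ppf(0.4, g2[0], scale=1 / g2[1]))
    lo = max(lo, 1e-12)
    while cdf(hi) < 0.05:
        hi *= 2
    while cdf(lo) > 0.05:
        lo /= 2
    ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-10)
    return (float(ebgm), float(ebgm05))


# ---------------------------------------------------------------------------
# multiplicity, verdicts, annotation


def bonferroni(p_raw: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, p·m); m defaults to len(p_raw)."""
    p = np.asarray(p_raw, float)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


@dataclass
class SignalRecord:
    """All four algorithms' statistics and verdicts for one PT."""

    pt: str
    soc: str
    a: int
    b: int
    c: int
    d: int
    expected: float
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    p_raw: float
    p_adj: float = math.nan
    positive_by: dict[str, bool] = field(default_factory=dict)
    consensus: bool = False
    flags: frozenset[str] = frozenset()


def consensus_signal(rec: SignalRecord,
                     thresholds: SignalThresholds | None = None
                     ) -> tuple[bool, dict[str, bool]]:
    """Apply the four per-algorithm criteria; an undefined statistic gives a
    conservative negative verdict for that algorithm."""
    th = thresholds or SignalThresholds()

    def ok(x: float) -> bool:
        return x is not None and not math.isnan(x)

    verdicts = {
        "ROR": bool(rec.a >= th.min_cases and ok(rec.ror_lo)
                    and rec.ror_lo > th.ror_lo),
        "PRR": bool(rec.a >= th.min_cases and ok(rec.prr) and ok(rec.chi2)
                    and rec.prr >= th.prr_min and rec.chi2 >= th.chi2_min),
        "BCPNN": bool(ok(rec.ic025) and rec.ic025 > th.ic025_min),
        "MGPS": bool(ok(rec.ebgm05) and rec.ebgm05 >= th.ebgm05_min),
    }
    return all(verdicts.values()), verdicts


def annotate(rec: SignalRecord,
             ime_list: Iterable[str] | None = None,
             dme_list: Iterable[str] | None = None,
             label_terms: Iterable[str] | None = None) -> SignalRecord:
    """Flag a record as IME / DME (exact case-insensitive PT match) and as
    ``unexpected`` when it is a consensus signal absent from the label."""
    flags = set()
    pt = rec.pt.lower()
    if ime_list is not None and pt in {t.lower() for t in ime_list}:
        flags.add("IME")
    if dme_list is not None and pt in {t.lower() for t in dme_list}:
        flags.add("DME")
    if label_terms is not None and rec.consensus and pt not in {
            t.lower() for t in label_terms}:
        flags.add("unexpected")
    return replace(rec, flags=frozenset(flags))


# ---------------------------------------------------------------------------
# whole-screen driver


def _report_pt_pairs(cases: CaseSet) -> pd.DataFrame:
    reac = cases.reactions
    df = pd.DataFrame({"caseid": reac["CASEID"], "pt": reac["PT"].astype(str)})
    return df.drop_duplicates()


def universe_drug_event_counts(universe: CaseSet) -> tuple[np.ndarray, np.ndarray]:
    """(a, E) for every drug–event pair of the universe, the MGPS prior's
    training set.  Drugs are normalised generic names (PROD_AI when present,
    else DRUGNAME); the unit is the deduplicated report."""
    drug = universe.drugs
    name = drug["PROD_AI"].where(
        drug.get("PROD_AI", pd.Series(index=drug.index)).notna(),
        drug["DRUGNAME"]) if "PROD_AI" in drug.columns else drug["DRUGNAME"]
    dd = pd.DataFrame({
        "caseid": drug["CASEID"],
        "drug": name.astype(str).str.upper().str.replace(r"[^A-Z0-9]", "",
                                                         regex=True),
    }).drop_duplicates()
    pp = _report_pt_pairs(universe)
    n = len(universe)
    n_drug = dd.groupby("drug")["caseid"].nunique()
    n_pt = pp.groupby("pt")["caseid"].nunique()
    pairs = dd.merge(pp, on="caseid").groupby(["drug", "pt"])["caseid"].nunique()
    a = pairs.to_numpy(float)
    idx = pairs.index
    e = (n_drug.loc[idx.get_level_values(0)].to_numpy(float)
         * n_pt.loc[idx.get_level_values(1)].to_numpy(float)) / n
    return a, e


def screen(cohort: CaseSet, universe: CaseSet,
           pt_soc: dict[str, str] | None = None,
           thresholds: SignalThresholds | None = None,
           ic_method: str = "noren",
           prior: PriorParams | None = None,
           ime_list: Iterable[str] | None = None,
           dme_list: Iterable[str] | None = None,
           label_terms: Iterable[str] | None = None,
           ) -> tuple[list[SignalRecord], PriorParams]:
    """Run the full four-algorithm screen over every PT reported in the cohort.

    Returns one :class:`SignalRecord` per PT (with Bonferroni-adjusted p over
    the number of PTs tested) and the fitted MGPS prior.
    """
    if prior is None:
        prior = mgps_fit(universe_drug_event_counts(universe))

    cohort_pairs = _report_pt_pairs(cohort)
    universe_pairs = _report_pt_pairs(universe)
    cohort_ids = set(cohort.caseids)
    n_universe = len(universe)
    n_cohort = len(cohort)

    pt_counts_cohort = cohort_pairs.groupby("pt")["caseid"].nunique()
    pt_counts_universe = universe_pairs.groupby("pt")["caseid"].nunique()

    records: list[SignalRecord] = []
    for pt, a in pt_counts_cohort.items():
        a = int(a)
        c = int(pt_counts_universe.get(pt, a)) - a
        b = n_cohort - a
        d = n_universe - n_cohort - c
        t = ContingencyTable(a, b, c, d)
        ror, ror_lo, ror_hi = ror_stats(t)
        prr, prr_lo, prr_hi, chi2 = prr_stats(t)
        ic, ic025 = bcpnn_ic(t, method=ic_method)
        ebgm, ebgm05 = ebgm_stats(t, prior)
        rec = SignalRecord(
            pt=str(pt), soc=(pt_soc or {}).get(str(pt), ""),
            a=a, b=b, c=c, d=d, expected=t.expected,
            ror=ror, ror_lo=ror_lo, ror_hi=ror_hi,
            prr=prr, prr_lo=prr_lo, prr_hi=prr_hi, chi2=chi2,
            ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
            p_raw=chi2_pvalue(t),
        )
        records.append(rec)

    p_adj = bonferroni([r.p_raw for r in records])
    out = []
    for rec, p in zip(records, p_adj):
        rec.p_adj = float(p)
        rec.consensus, rec.positive_by = consensus_signal(rec, thresholds)
        rec = annotate(rec, ime_list, dme_list, label_terms)
        out.append(rec)
    return out, prior


def records_to_frame(records: Sequence[SignalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in (
            "pt", "soc", "a", "b", "c", "d", "expected", "ror", "ror_lo",
            "ror_hi", "prr", "prr_lo", "prr_hi", "chi2", "ic", "ic025",
            "ebgm", "ebgm05", "p_raw", "p_adj", "consensus")}
        for alg, v in r.positive_by.items():
            d[f"positive_{alg.lower()}"] = v
        d["flags"] = "|".join(sorted(r.flags))
        rows.append(d)
    return pd.DataFrame(rows)
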