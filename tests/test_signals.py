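import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from faerspv.signals import (CANONICAL_START, ContingencyTable, PriorParams,
                             SignalRecord, SignalThresholds, _mixture_loglik,
                             annotate, bcpnn_ic, bonferroni, build_contingency,
                             chi2_pvalue, consensus_signal, ebgm_stats,
                             mgps_fit, prr_stats, ror_stats)

from conftest import make_caseset

T = ContingencyTable(10, 90, 100, 9900)


def _record(**kw):
    base = dict(pt="x", soc="", a=10, b=90, c=100, d=9900, expected=1.09,
                ror=11.0, ror_lo=5.56, ror_hi=21.76, prr=10.0, prr_lo=5.38,
                prr_hi=18.58, chi2=66.3, ic=2.72, ic025=1.69, ebgm=8.0,
                ebgm05=4.0, p_raw=1e-10)
    base.update(kw)
    return SignalRecord(**base)


# ---------------------------------------------------------------------------
# contingency construction


def test_contingency_counts_against_hand_tally():
    # universe of 100 reports, cohort of 10; PT on 4 cohort + 6 outside
    universe = {str(i): ["Other"] for i in range(100)}
    for i in range(4):
        universe[str(i)] = ["Target PT"]
    for i in range(10, 16):
        universe[str(i)] = ["Target PT"]
    uni = make_caseset(universe)
    coh = make_caseset({str(i): universe[str(i)] for i in range(10)})
    t = build_contingency(coh, uni, "Target PT")
    assert (t.a, t.b, t.c, t.d) == (4, 6, 6, 84)
    assert t.n == 100


def test_contingency_pt_absent_everywhere():
    uni = make_caseset({str(i): ["Other"] for i in range(20)})
    coh = make_caseset({str(i): ["Other"] for i in range(5)})
    t = build_contingency(coh, uni, "Ghost")
    assert (t.a, t.b, t.c, t.d) == (0, 5, 0, 15)


def test_contingency_requires_subset():
    uni = make_caseset({"1": ["x"], "2": ["x"]})
    coh = make_caseset({"3": ["x"]})
    with pytest.raises(ValueError, match="subset"):
        build_contingency(coh, uni, "x")


def test_negative_cells_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# ROR / PRR / chi2 — frozen values from an independent script


def test_ror_point_and_interval():
    ror, lo, hi = ror_stats(T)
    assert ror == pytest.approx(11.0)
    assert lo == pytest.approx(5.559585, rel=1e-5)
    assert hi == pytest.approx(21.764216, rel=1e-5)


def test_ror_is_one_under_proportional_margins():
    ror, _, _ = ror_stats(ContingencyTable(5, 50, 10, 100))
    assert ror == pytest.approx(1.0)


def test_prr_point_interval_and_chi2():
    prr, lo, hi, chi2 = prr_stats(T)
    assert prr == pytest.approx(10.0)
    assert lo == pytest.approx(5.382215, rel=1e-5)
    assert hi == pytest.approx(18.579710, rel=1e-5)
    # Yates-corrected statistic cross-checked against scipy
    ref = stats.chi2_contingency([[10, 90], [100, 9900]], correction=True)
    assert chi2 == pytest.approx(ref.statistic, rel=1e-10)


def test_prr_null_table():
    prr, _, _, _ = prr_stats(ContingencyTable(5, 50, 10, 100))
    assert prr == pytest.approx(1.0)


def test_zero_cell_gives_flagged_nan_not_infinity():
    ror, lo, hi = ror_stats(ContingencyTable(0, 10, 5, 100))
    assert math.isnan(ror)
    # a >= 1 with a single zero cell: Haldane-Anscombe applies
    ror2, lo2, hi2 = ror_stats(ContingencyTable(3, 10, 0, 100))
    assert np.isfinite([ror2, lo2, hi2]).all()


def test_chi2_pvalue_switches_to_fisher_for_small_expected():
    t = ContingencyTable(3, 7, 2, 200)  # expected a well under 5
    ref = stats.fisher_exact([[3, 7], [2, 200]])[1]
    assert chi2_pvalue(t) == pytest.approx(ref)


@settings(max_examples=200, deadline=None)
@given(st.integers(1, 200), st.integers(1, 500), st.integers(1, 500),
       st.integers(1, 5000))
def test_ror_and_prr_sit_on_same_side_of_one(a, b, c, d):
    """Algebraic identity: ROR and PRR always deviate from 1 in the same
    direction on all-positive tables."""
    t = ContingencyTable(a, b, c, d)
    ror, _, _ = ror_stats(t)
    prr, _, _, _ = prr_stats(t)
    assert (ror - 1) * (prr - 1) >= -1e-12
    if ror > 1:
        assert ror >= prr - 1e-12  # OR further from 1 than the ratio


def test_background_report_moves_only_d_and_expected():
    t1 = ContingencyTable(4, 6, 6, 84)
    t2 = ContingencyTable(4, 6, 6, 85)
    assert t2.n == t1.n + 1
    assert t2.expected < t1.expected


# ---------------------------------------------------------------------------
# BCPNN


def test_ic_hand_value():
    ic, _ = bcpnn_ic(T)
    assert T.expected == pytest.approx(1.089109, rel=1e-5)
    assert ic == pytest.approx(2.724099, rel=1e-4)


def test_ic_zero_when_observed_equals_expected():
    t = ContingencyTable(2, 18, 18, 162)  # E = 20*20/200 = 2 = a
    ic, _ = bcpnn_ic(t)
    assert ic == pytest.approx(0.0, abs=1e-12)


def test_ic025_frozen_value_and_orderings():
    ic, ic025 = bcpnn_ic(T, method="noren")
    assert ic025 == pytest.approx(1.693957, rel=1e-4)
    assert ic025 < ic
    _, approx025 = bcpnn_ic(T, method="approx")
    assert approx025 < ic


@settings(max_examples=100, deadline=None)
@given(st.integers(1, 100), st.integers(0, 300), st.integers(0, 300),
       st.integers(0, 3000))
def test_ic025_below_ic_for_positive_counts(a, b, c, d):
    ic, ic025 = bcpnn_ic(ContingencyTable(a, b, c, d))
    assert ic025 < ic


# ---------------------------------------------------------------------------
# MGPS


@pytest.fixture(scope="module")
def null_prior():
    rng = np.random.default_rng(5)
    e = np.exp(rng.uniform(np.log(0.5), np.log(200), 800))
    a = rng.poisson(e)
    return mgps_fit((a, e))


def test_null_prior_concentrates_near_one(null_prior):
    p = null_prior
    mean = p.w * p.alpha1 / p.beta1 + (1 - p.w) * p.alpha2 / p.beta2
    assert 0.5 <= mean <= 2.0


def test_single_component_prior_recovered():
    rng = np.random.default_rng(5)
    e = np.exp(rng.uniform(np.log(0.5), np.log(200), 800))
    lam = rng.gamma(0.2, 10.0, size=800)  # Ga(alpha=0.2, rate=0.1)
    a = rng.poisson(lam * e)
    p = mgps_fit((a, e))
    w_dom = max(p.w, 1 - p.w)
    alpha, beta = ((p.alpha1, p.beta1) if p.w >= 0.5 else (p.alpha2, p.beta2))
    assert w_dom > 0.9
    assert alpha == pytest.approx(0.2, rel=0.5)
    assert beta == pytest.approx(0.1, rel=0.5)


def test_fit_improves_on_canonical_start(null_prior):
    rng = np.random.default_rng(5)
    e = np.exp(rng.uniform(np.log(0.5), np.log(200), 800))
    a = rng.poisson(e)
    start_ll = _mixture_loglik(np.array(CANONICAL_START.as_tuple()), a, e)
    assert null_prior.loglik >= start_ll


# ---------------------------------------------------------------------------
# EBGM


def test_ebgm_near_maximum_likelihood_for_large_counts():
    # a=1000, E=100: shrinkage is negligible, EBGM ~ a/E = 10
    t = ContingencyTable(1000, 9000, 9000, 981000)
    assert t.expected == pytest.approx(100.0)
    ebgm, ebgm05 = ebgm_stats(t, CANONICAL_START)
    assert ebgm == pytest.approx(10.0, rel=0.05)
    assert ebgm05 < ebgm
    assert ebgm05 == pytest.approx(10.0, rel=0.10)


def test_degenerate_prior_pins_ebgm_at_one():
    prior = PriorParams(alpha1=1e5, beta1=1e5, alpha2=1e5, beta2=1e5, w=0.5)
    for a in (1, 10, 50):
        t = ContingencyTable(a, 50, 50, 5000)
        ebgm, _ = ebgm_stats(t, prior)
        assert ebgm == pytest.approx(1.0, rel=0.05)


def test_ebgm_shrinks_toward_null(null_prior):
    for a, b, c, d in [(6, 94, 200, 9700), (20, 80, 200, 9700),
                       (12, 188, 300, 19500)]:
        t = ContingencyTable(a, b, c, d)
        rr = t.a / t.expected
        assert rr > 1
        ebgm, _ = ebgm_stats(t, null_prior)
        assert 1.0 - 1e-9 < ebgm < rr


def test_ebgm_monotone_in_count(null_prior):
    values = []
    for a in range(1, 30):
        t = ContingencyTable(a, 100, 200, 10000)
        # fix E by adjusting nothing: E changes little with a here
        values.append(ebgm_stats(t, null_prior)[0])
    assert all(x < y for x, y in zip(values, values[1:]))


# ---------------------------------------------------------------------------
# multiplicity + verdicts


def test_bonferroni_arithmetic():
    out = bonferroni([0.001], m=50)
    assert out[0] == pytest.approx(0.05)
    assert bonferroni([0.5], m=10)[0] == 1.0


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
def test_bonferroni_preserves_ranking(ps):
    adj = bonferroni(ps)
    order_raw = np.argsort(ps, kind="stable")
    assert (np.sort(adj[order_raw]) == adj[order_raw]).all()


def test_count_floor_blocks_consensus():
    rec = _record(a=2, ror=500.0, ror_lo=50.0)
    ok, verdicts = consensus_signal(rec)
    assert not ok
    assert not verdicts["ROR"] and not verdicts["PRR"]


def test_consensus_requires_all_four():
    rec = _record()
    ok, verdicts = consensus_signal(rec)
    assert ok and all(verdicts.values())
    ok2, v2 = consensus_signal(_record(ebgm05=1.5))
    assert not ok2 and not v2["MGPS"] and v2["ROR"]


def test_undefined_statistic_is_conservative():
    ok, verdicts = consensus_signal(_record(ror=math.nan, ror_lo=math.nan))
    assert not verdicts["ROR"] and not ok


def test_thresholds_configurable():
    rec = _record(a=2)
    ok, _ = consensus_signal(rec, SignalThresholds(min_cases=1))
    assert ok


# ---------------------------------------------------------------------------
# annotation


def test_annotation_flags():
    rec = _record(pt="Anaphylactic reaction", consensus=True)
    out = annotate(rec, ime_list=["ANAPHYLACTIC REACTION", "Colitis"],
                   dme_list=["anaphylactic reaction"],
                   label_terms=["Diarrhoea"])
    assert out.flags == {"IME", "DME", "unexpected"}


def test_on_label_signal_not_unexpected():
    rec = _record(pt="Colitis", consensus=True)
    out = annotate(rec, label_terms=["colitis"])
    assert "unexpected" not in out.flags


def test_no_lists_no_flags():
    assert annotate(_record()).flags == frozenset()
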