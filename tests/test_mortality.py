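import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

import faerspv as pv
from faerspv.mortality import (breslow_loglik, build_design_matrix, cox_fit,
                               lasso_cox_select, risk_score,
                               stratify_and_test, time_dependent_roc)
from faerspv.simulate import DEFAULT_MORTALITY_COEFS, mortality_sim_config

# the published final-model coefficients
PUBLISHED_COEFS = {
    "immune_thrombocytopenia": 2.5828,
    "immune_mediated_dermatitis": 2.3273,
    "immune_mediated_enterocolitis": 1.1487,
    "immune_mediated_myocarditis": 1.8384,
    "multiple_organ_dysfunction_syndrome": 2.0168,
    "myocarditis": 1.5122,
}


def _surv_frame(rng, n=300, beta=0.8, prev=0.3, base=0.01, follow=365.0):
    x = rng.binomial(1, prev, n)
    z = rng.normal(0, 1, n)
    h = base * np.exp(beta * x + 0.3 * z)
    t = rng.exponential(1 / h)
    event = t <= follow
    return pd.DataFrame({
        "time_days": np.maximum(np.minimum(t, follow), 0.5),
        "event": event.astype(int),
        "v1": x,
        "v2": z,
    })


# ---------------------------------------------------------------------------
# design matrix


@pytest.fixture(scope="module")
def sim_design():
    raw, ledger = pv.generate(mortality_sim_config(seed=1))
    cases = pv.deduplicate(raw)
    cands = list(DEFAULT_MORTALITY_COEFS) + ["Nausea", "Rash", "Pyrexia"]
    df = build_design_matrix(cases, cands, censor_days=ledger.censor_days)
    return df, ledger


def test_design_matrix_shapes_and_coding(sim_design):
    df, ledger = sim_design
    assert df["event"].sum() == ledger.n_fatal
    assert set(df["male"].unique()) <= {0, 1}
    assert (df["time_days"] > 0).all()
    pt_cols = [c for c in df.columns if c.startswith("pt_")]
    assert set(df[pt_cols].to_numpy().ravel()) <= {0, 1}


def test_candidate_columns_respect_case_floor():
    raw, ledger = pv.generate(mortality_sim_config(seed=2))
    cases = pv.deduplicate(raw)
    df = build_design_matrix(cases, list(DEFAULT_MORTALITY_COEFS)
                             + ["No-such-term"], min_pt_cases=2)
    assert "pt_no_such_term" not in df.columns
    for pt in DEFAULT_MORTALITY_COEFS:  # all planted at ~6% prevalence
        assert "pt_" + pt.lower().replace(" ", "_").replace("-", "_") in df.columns


def test_cases_with_missing_age_or_sex_excluded(cohort):
    df = build_design_matrix(
        cohort, ["Immune-mediated enterocolitis"],
        drug_patterns=["durvalumab", "imfinzi", "tremelimumab", "imjudo"])
    cc = cohort.cases.set_index("caseid")
    assert cc.loc[df.index, "sex"].isin(["F", "M"]).all()
    assert cc.loc[df.index, "age_years"].notna().all()


def test_too_few_records_is_error():
    raw, _ = pv.generate(mortality_sim_config(n_cohort=30, seed=3))
    cases = pv.deduplicate(raw)
    small = cases.restrict(list(cases.caseids[:10]), "head")
    with pytest.raises(ValueError, match="identifiable"):
        build_design_matrix(small, [])


# ---------------------------------------------------------------------------
# LASSO path


def test_infinite_penalty_zeroes_every_coefficient():
    rng = np.random.default_rng(0)
    df = _surv_frame(rng)
    path = lasso_cox_select(df, folds=3, seed=0,
                            alphas=np.array([50.0, 100.0]))
    assert (path.coefs.to_numpy() == 0).all(axis=0)[path.coefs.columns.get_loc(100.0)]


def test_zero_penalty_limit_matches_unpenalized_cox():
    rng = np.random.default_rng(3)
    df = _surv_frame(rng)
    path = lasso_cox_select(df, folds=3, seed=0, standardize=False,
                            alphas=np.array([1e-9, 1e-2, 1e-1]))
    cph = CoxPHFitter().fit(df, "time_days", "event")
    smallest = path.coefs.columns.min()
    np.testing.assert_allclose(path.coefs[smallest].to_numpy(),
                               cph.params_.to_numpy(), atol=1e-4)


def test_single_strong_factor_selected():
    """One planted factor (HR 8) among 20 noise indicators, n=400."""
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n = 400
        x = rng.binomial(1, 0.25, n)
        noise = rng.binomial(1, 0.15, size=(n, 20))
        h = 0.004 * np.exp(np.log(8) * x)
        t = rng.exponential(1 / h)
        df = pd.DataFrame(noise, columns=[f"n{i}" for i in range(20)])
        df.insert(0, "planted", x)
        df.insert(0, "event", (t <= 365).astype(int))
        df.insert(0, "time_days", np.maximum(np.minimum(t, 365), 0.5))
        path = lasso_cox_select(df, folds=5, seed=seed)
        hits += "planted" in path.selected
    assert hits == 5


def test_breslow_loglik_matches_lifelines():
    rng = np.random.default_rng(8)
    df = _surv_frame(rng, n=150)
    cph = CoxPHFitter().fit(df[["time_days", "event", "v1", "v2"]],
                            "time_days", "event")
    ours = breslow_loglik(df[["v1", "v2"]].to_numpy(),
                          df["time_days"].to_numpy(),
                          df["event"].to_numpy(),
                          cph.params_.to_numpy())
    # continuous times → no ties → Breslow == Efron == lifelines loglik
    assert ours == pytest.approx(cph.log_likelihood_, rel=1e-6)


# ---------------------------------------------------------------------------
# Cox fit


def test_cox_recovers_planted_log_hazard():
    rng = np.random.default_rng(42)
    df = _surv_frame(rng, n=500, beta=np.log(2))
    out = cox_fit(df, ["v1", "v2"])
    assert out.loc["v1", "hr_lo"] <= 2.0 <= out.loc["v1", "hr_hi"]
    assert out.loc["v1", "independent"]


def test_cox_time_scale_invariance():
    rng = np.random.default_rng(6)
    df = _surv_frame(rng)
    out1 = cox_fit(df, ["v1", "v2"])
    df2 = df.assign(time_days=df["time_days"] * 2)
    out2 = cox_fit(df2, ["v1", "v2"])
    np.testing.assert_allclose(out1["hr"], out2["hr"], rtol=1e-6)


def test_null_covariate_p_values_are_uniform():
    rng = np.random.default_rng(13)
    ps = []
    for _ in range(60):
        df = _surv_frame(rng, n=200, beta=0.0)
        ps.append(cox_fit(df, ["v1"]).loc["v1", "p"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# risk score


def test_published_score_single_factor():
    record = {k: 0.0 for k in PUBLISHED_COEFS}
    record["immune_thrombocytopenia"] = 1.0
    assert risk_score(record, PUBLISHED_COEFS) == pytest.approx(2.5828)


def test_published_score_two_factors():
    record = {k: 0.0 for k in PUBLISHED_COEFS}
    record["immune_mediated_enterocolitis"] = 1.0
    record["myocarditis"] = 1.0
    assert risk_score(record, PUBLISHED_COEFS) == pytest.approx(2.6609)


def test_score_zero_when_all_indicators_zero():
    record = {k: 0.0 for k in PUBLISHED_COEFS}
    assert risk_score(record, PUBLISHED_COEFS) == 0.0


def test_unknown_variable_is_error():
    record = {"not_a_model_variable": 1.0}
    with pytest.raises(ValueError, match="unknown"):
        risk_score(record, PUBLISHED_COEFS)


# ---------------------------------------------------------------------------
# stratification


def test_median_split_ties_to_low():
    rec = pd.DataFrame({"time_days": [10.0, 20, 30, 40],
                        "event": [1, 0, 1, 0]})
    out = stratify_and_test(np.array([0.0, 0.0, 1.0, 1.0]), rec)
    assert out.median_cutoff == 0.5
    assert (out.group == "high").sum() == 2


def test_degenerate_scores_single_group():
    rec = pd.DataFrame({"time_days": [10.0, 20, 30, 40],
                        "event": [1, 0, 1, 0]})
    out = stratify_and_test(np.zeros(4), rec)
    assert out.logrank_p is None


def test_planted_group_separation_detected():
    rng = np.random.default_rng(17)
    n = 300
    risk = rng.binomial(1, 0.5, n)
    h = 0.003 * np.exp(np.log(5) * risk)
    t = rng.exponential(1 / h)
    rec = pd.DataFrame({"time_days": np.maximum(np.minimum(t, 365), 0.5),
                        "event": (t <= 365).astype(int)})
    out = stratify_and_test(risk + rng.normal(0, 0.01, n), rec)
    assert out.logrank_p < 0.01


def test_permuted_scores_break_association():
    rng = np.random.default_rng(23)
    n = 300
    risk = rng.binomial(1, 0.5, n)
    h = 0.003 * np.exp(np.log(5) * risk)
    t = rng.exponential(1 / h)
    rec = pd.DataFrame({"time_days": np.maximum(np.minimum(t, 365), 0.5),
                        "event": (t <= 365).astype(int)})
    ps = []
    for _ in range(20):
        ps.append(stratify_and_test(
            rng.permutation(risk) + rng.normal(0, 0.01, n), rec).logrank_p)
    assert 0.15 < np.median(ps) < 0.85


# ---------------------------------------------------------------------------
# time-dependent ROC


def _roc_frame(rng, n=1000, informative=True):
    score = rng.normal(0, 1, n)
    h = 0.004 * np.exp((1.0 if informative else 0.0) * score)
    t = rng.exponential(1 / h)
    return score, pd.DataFrame({
        "time_days": np.maximum(np.minimum(t, 365), 0.5),
        "event": (t <= 365).astype(int)})


def test_uninformative_score_has_auc_half():
    rng = np.random.default_rng(31)
    score, rec = _roc_frame(rng, informative=False)
    roc = time_dependent_roc(score, rec, horizons=(60.0,))
    assert roc["auc"].iloc[0] == pytest.approx(0.5, abs=0.05)


def test_perfect_separation_gives_auc_one():
    rec = pd.DataFrame({
        "time_days": [5.0, 10, 20, 100, 200, 300, 320, 365],
        "event": [1, 1, 1, 0, 0, 0, 0, 0]})
    score = np.array([10.0, 9, 8, 1, 2, 0.5, 1.5, 0.2])
    roc = time_dependent_roc(score, rec, horizons=(30.0,))
    assert roc["auc"].iloc[0] == pytest.approx(1.0)


def test_matches_pairwise_auc_without_censoring():
    """With every case observed through the horizon, AUC(t) equals the
    empirical probability a case (event by t) outranks a control."""
    rng = np.random.default_rng(37)
    score, rec = _roc_frame(rng, n=400)
    rec.loc[rec["event"] == 0, "time_days"] = 365.0  # full follow-up
    h = 60.0
    roc = time_dependent_roc(score, rec, horizons=(h,))
    case = (rec["event"] == 1) & (rec["time_days"] <= h)
    control = rec["time_days"] > h
    sc, sk = score[case.to_numpy()], score[control.to_numpy()]
    pairs = (sc[:, None] > sk[None, :]).mean() + 0.5 * (
        sc[:, None] == sk[None, :]).mean()
    assert roc["auc"].iloc[0] == pytest.approx(pairs, abs=0.02)


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(41)
    score, rec = _roc_frame(rng, n=400)
    roc1 = time_dependent_roc(score, rec, horizons=(60.0,))
    roc2 = time_dependent_roc(np.exp(3 * score), rec, horizons=(60.0,))
    assert roc1["auc"].iloc[0] == pytest.approx(roc2["auc"].iloc[0], abs=1e-9)


def test_horizon_without_events_flagged():
    rec = pd.DataFrame({"time_days": [100.0, 200, 300, 350],
                        "event": [0, 1, 0, 0]})
    roc = time_dependent_roc(np.arange(4.0), rec, horizons=(30.0,))
    assert np.isnan(roc["auc"].iloc[0])
    assert roc["flag"].iloc[0] == "no events"
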