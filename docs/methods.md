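# Methods

This note records the models behind `faerspv`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer would otherwise have to reverse-engineer.

## Cohort extraction

FAERS delivers one row per *submission* (`primaryid`); a case (`caseid`)
may be resubmitted many times. Deduplication keeps, per case, the
submission with the latest `FDA_DT`, breaking ties by the largest
`primaryid` — the usual community reading of FDA-recommended practice.
Dates are `YYYYMMDD` integers; partial dates (`YYYYMM`, `YYYY`) are parsed
with mid-period imputation and flagged by precision so downstream stages
can exclude them (TTO does, by default).

Age normalisation: `AGE_COD` ∈ DEC×10, YR×1, MON÷12, WK÷52, DY÷365,
HR÷8760; ages above 120 years become missing. Age groups are <18, 18–64,
65–79, ≥80. Drug matching is a case-insensitive substring test after
stripping non-alphanumerics, applied to DRUGNAME and PROD_AI; no
edit-distance matching — deterministic and auditable beats marginally
higher recall here. A combination cohort requires every agent group to
match in an allowed role (`PS/SS/C/I` by default; `PS` only in strict
mode). Outcome code note: OUTC_COD `CA` and `RI` are folded into the
"Other serious outcomes" category, which keeps five serious categories in
the demographic table; the serious roll-up is their sum, counting a report
once per distinct category.

The disproportionality denominator is the full deduplicated universe
(including reports without a usable PT); restricting to PT-bearing reports
changes d only and, at FAERS scale, nothing of substance.

## Disproportionality

All four statistics use the report-level 2×2 table; a report contributes
at most once per cell regardless of how often a PT repeats on it.

* ROR and PRR follow the standard lognormal-CI forms. Zero-cell handling:
  Haldane–Anscombe +0.5 on all four cells, applied only when a ≥ 1 and
  exactly one of b, c, d is zero; a = 0 is "no signal" by definition and
  yields flagged NaNs rather than silent infinities.
* BCPNN: IC = log₂[(a+0.5)/(E+0.5)]. Two credibility-interval variants are
  implemented because the literature uses both: the default takes the
  exact 2.5% quantile of the Ga(a+0.5, rate E+0.5) posterior on the
  observed/expected ratio; the closed-form
  IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2) is available via
  `ic_method="approx"`.
* MGPS: the DuMouchel prior — a two-component gamma mixture on the
  relative reporting rate — is fitted by marginal maximum likelihood
  (each component's marginal for a given E is negative binomial) with
  bounded L-BFGS-B from the canonical start (0.2, 0.1, 2, 4, ⅓) and
  jittered multi-starts as fallback; hyperparameters are bounded in
  [1e-4, 50]. On null data the fit correctly degenerates toward a point
  mass at 1 (large α ≈ β), which is why the large-count
  "EBGM → a/E" sanity check uses a fixed proper prior. The prior is
  fitted on all drug–event pairs of the *universe* (that is the shrinker's
  design), not the cohort only. EBGM uses the digamma closed form for
  E[log₂ λ]; EBGM05 is found by Brent root-finding on the posterior
  mixture CDF.
* Per-PT p-values: Yates-corrected χ² on the 2×2, switching to Fisher's
  exact test when any expected cell is below 5; Bonferroni over the number
  of PTs tested. These drive the volcano export; signal calls themselves
  use the four-algorithm thresholds.
* Consensus thresholds (all configurable): a ≥ 3 with ROR lower CI > 1;
  a ≥ 3, PRR ≥ 2, χ² ≥ 4; IC025 > 0; EBGM05 ≥ 2. An undefined statistic
  gives that algorithm a negative verdict — conservative by construction.

## Time to onset

TTO = EVENT_DT − min(START_DT over the suspect drugs' therapy rows), in
days. Exclusions (missing date, event before start, precision worse than a
day) are logged; month-precision dates can be admitted with mid-month
imputation via a flag. EVENT_DT is report-level in FAERS, so all PTs of a
case share its interval; distribution summaries are AE-level, while KM and
log-rank use the patient level (first event) to avoid within-case
correlation. Interval bins are half-open: [0,30), [30,60), [60,90),
[90,180), [180,365), [365,∞). The median CI is the distribution-free
binomial order-statistic interval.

Weibull fits are unweighted MLEs (lifelines) with delta-method CIs on the
log scale back-transformed; zero-day onsets are shifted +0.5 day for the
likelihood only (binning keeps them in [0,30)). Fits require n ≥ 10;
smaller PTs are reported "insufficient". The shape-CI classification
(early / random / wear-out failure) is exhaustive and mutually exclusive
whenever lo ≤ β ≤ hi.

A note on log-rank benchmarks: two Weibulls with different shapes but a
common scale have survival curves that cross at the common scale, a known
blind spot of the unweighted log-rank test; power checks in the test suite
therefore use stochastically ordered arms.

## Mortality risk model

One record per case with complete sex, age and dates. Time runs from
therapy start to fatal-AE onset (OUTC_COD contains `DE`); non-fatal cases
are censored at their last recorded event date — a spontaneous-report
database has no follow-up, so this is the only defensible real-data
scheme. On simulated data the generator's death process runs over a known
365-day window, and `build_design_matrix(..., censor_days=...)` applies
that administrative censoring instead; the distinction matters (see the
identifiability experiment below). Candidate covariates: sex (male = 1),
age in years (continuous), and indicators for consensus-positive PTs
occurring in ≥ 2 usable cases (the floor is configurable). Fewer than 20
usable records is an error — a Cox model below that is noise.

Selection: L1-penalised Cox (scikit-survival's Coxnet, l1_ratio = 1) over
a log-spaced α grid with columns standardised (glmnet convention); 10-fold
cross-validated partial-likelihood deviance in the Verweij–van Houwelingen
form, −2·[ll(all; β_fold) − ll(train; β_fold)], computed with our own
Breslow partial likelihood; λ* is the deviance minimiser (not the 1-SE
rule — the CV-curve minimum is the stated design). The final model is an
unpenalised lifelines Cox fit (Efron ties) on the selected variables; Wald
p < 0.05 marks "independent" factors, with no further multiplicity
correction (raw Wald p is what such analyses report). Risk score =
Σβᵢxᵢ over final-model variables; the high/low split is at the median with
ties to low; AUC(t) is the IPCW cumulative-case/dynamic-control estimator
at 30/60/90 days.

## Synthetic generator

The generator emulates the structure the pipeline consumes, with planted
quantities recorded in a `TruthLedger`:

* **Reporting ratios.** Background reports draw 1 + min(4, Poisson(1.2))
  PTs from a fixed marginal; cohort reports draw from a tilted marginal in
  which each planted PT's per-draw probability is *exactly* λ times its
  background probability, with the unplanted mass absorbing the
  renormalisation. (Renormalising over all PTs, planted included, would
  deflate every planted ratio by the total planted mass — ≈12% at the
  defaults — making λ unrecoverable at its own tolerance.) Planted mass
  ≥ 1 is a hard error. Default planted PTs, their λ (chosen to match
  published reporting ratios for this drug pair) and their cohort shares
  give a 715-report cohort with per-PT counts of the published order.
* **Demographics.** Cohort marginals (sex, age group, reporter occupation,
  country, year) copied from the published demographic table, missingness
  included as a category; ages drawn uniformly within bins.
* **Onset times.** Per-PT Weibull models for three PTs — shape 0.41/scale
  30, 1.32/45, 1.97/60, the published temporal patterns — and a shared
  Weibull(1, 36) (median ≈ 25 days) for everything else. A report with
  several modelled PTs keeps the first model in declaration order; the
  ledger records each case's assigned model so recovery checks can
  condition on it.
* **Mortality.** Exponential baseline hazard 6×10⁻⁴/day, log-hazard
  coefficients on six risk-factor PTs equal to the published risk-score
  coefficients, window 365 days. Deaths get OUTC_COD `DE` and EVENT_DT
  moved to the death date — which is why onset-model recovery is evaluated
  on non-fatal reports (onset and death times are independent given the
  PT set, so this conditioning is unbiased). Non-fatal serious outcomes
  are drawn from a fixed marginal.
* **Noise processes.** Duplicate submissions (default 10%) as extra
  primaryids with earlier FDA_DT; per-field missingness for EVENT_DT
  (0.45), START_DT (0.50) and month-only event dates (0.10), calibrated so
  ≈190 of 715 cohort cases have complete day-precision TTO, as in the
  motivating dataset.

Identical seeds give bit-identical tables. The generator does **not**
emulate reporting dynamics (stimulated reporting, seasonality, secular
trends), drug-specific background event profiles, within-case correlation
of PT choices beyond the shared event date, or notification delay
structure — so green planted-truth tests demonstrate that the machinery
recovers known structure, not that real FAERS signals are causal or that
real-data power matches the simulated power.

## Problem sizes used in verification

* Default generator scale (20 000 background + 715 cohort reports)
  reproduces the motivating study's scale, including its limitation: only
  ~55 complete-case records with ~19 deaths reach the risk model, where
  penalised selection correctly returns an empty set.
* The planted-truth end-to-end run uses 30 000 background + 4 000 cohort
  reports with date missingness reduced to 0.25/0.25 so that every
  planted λ ≥ 10 PT has an expected count well above the a ≥ 3 floor and
  each onset-modelled PT retains ≥ 10 usable non-fatal records — the
  scale at which category recovery is statistically meaningful. At the
  lowest-count modelled PT (shape 1.32, n ≈ 12–30) the CI straddles 1 by
  width alone, so the check there is CI coverage of the planted shape
  rather than the category label.
* The mortality identifiability experiment (`mortality_sim_config`) uses
  complete-case cohorts of 700 with ≈230 events, risk-PT prevalence ≈6.5%
  per report (the published enterocolitis frequency), baseline hazard
  4×10⁻⁴/day, and the generator's administrative censoring. With
  onset-date censoring instead, all-six selection drops to ≈46% — and
  R's `cv.glmnet` (lambda.min) misses the same factor on the same data,
  i.e. the loss is informational, not an implementation artefact.
* The null false-positive check simulates 10 000 independent drug–event
  pairs (universe 100 000, cohort 1 000) and requires a consensus rate
  below 1%.

## Known limitations

* No legacy (pre-2012Q4) AERS schema, no XML dialect.
* No stratified or multi-drug (interaction) disproportionality; no
  competing-risk or cure models for onset; no external validation of the
  risk model — the motivating analysis has none either.
* IME/DME/label term lists are consumed as user-supplied files and never
  redistributed.
* The MGPS hyperparameter bounds ([1e-4, 50]) cap how degenerate the
  fitted prior can get; on strongly null data the fit pushes against the
  upper bound by design.
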