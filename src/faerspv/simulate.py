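"""Synthetic FAERS generator with planted, recoverable structure.

Emits the seven FAERS-format tables for a configurable mix of *background*
reports (arbitrary drugs and events, independent margins) and *cohort*
reports (both target agents plus the target indication) in which three kinds
of signal are planted and recorded in a :class:`TruthLedger`:

* **disproportionality** — each planted preferred term (PT) carries a
  reporting-ratio multiplier λ ≥ 1: inside the cohort its per-draw
  probability is exactly λ times its background probability (the remaining
  probability mass is taken proportionally from the unplanted PTs, so the
  planted ratio is exact rather than deflated by renormalisation);
* **time to onset** — per-PT Weibull(shape, scale) onset-time models;
* **mortality** — an exponential-baseline proportional-hazards process whose
  log-hazard is a linear function of risk-factor PT indicators; deaths within
  the follow-up window become OUTC_COD ``DE`` with EVENT_DT moved to the
  death date.

Duplicate submissions (extra primaryids with earlier FDA_DT) and per-field
missingness are injected at configurable rates.  Identical seeds give
bit-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import RawTables, write_quarter

# §-- default study conditions ------------------------------------------------

#: planted PTs: pt -> (SOC, reporting ratio λ, expected cohort PT-draw share)
DEFAULT_PLANTED: dict[str, tuple[str, float, float]] = {
    "Immune-mediated enterocolitis": ("Gastrointestinal disorders", 28.0, 0.026),
    "Liver disorder": ("Hepatobiliary disorders", 5.2, 0.025),
    "Immune-mediated hepatic disorder": ("Hepatobiliary disorders", 65.0, 0.021),
    "Colitis": ("Gastrointestinal disorders", 6.2, 0.0165),
    "Liver carcinoma ruptured": (
        "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
        11.8, 0.0146),
    "Cytokine release syndrome": ("Immune system disorders", 31.5, 0.012),
    "Immune-mediated dermatitis": ("Skin and subcutaneous tissue disorders",
                                   55.0, 0.0089),
    "Myocarditis": ("Cardiac disorders", 5.4, 0.0089),
    "Immune-mediated myocarditis": ("Cardiac disorders", 30.5, 0.0076),
    "Drug-induced liver injury": ("Hepatobiliary disorders", 6.7, 0.0076),
    "Multiple organ dysfunction syndrome":
        ("General disorders and administration site conditions", 4.5, 0.0057),
    "Immune thrombocytopenia": ("Blood and lymphatic system disorders",
                                8.0, 0.005),
    "Anaphylactic reaction": ("Immune system disorders", 10.0, 0.004),
    "Thyrotoxic crisis": ("Endocrine disorders", 65.0, 0.002),
}

DEFAULT_NOISE_PTS: tuple[tuple[str, str], ...] = (
    ("Nausea", "Gastrointestinal disorders"),
    ("Diarrhoea", "Gastrointestinal disorders"),
    ("Vomiting", "Gastrointestinal disorders"),
    ("Fatigue", "General disorders and administration site conditions"),
    ("Pyrexia", "General disorders and administration site conditions"),
    ("Headache", "Nervous system disorders"),
    ("Dizziness", "Nervous system disorders"),
    ("Rash", "Skin and subcutaneous tissue disorders"),
    ("Pruritus", "Skin and subcutaneous tissue disorders"),
    ("Alopecia", "Skin and subcutaneous tissue disorders"),
    ("Anaemia", "Blood and lymphatic system disorders"),
    ("Neutropenia", "Blood and lymphatic system disorders"),
    ("Decreased appetite", "Metabolism and nutrition disorders"),
    ("Dehydration", "Metabolism and nutrition disorders"),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders"),
    ("Cough", "Respiratory, thoracic and mediastinal disorders"),
    ("Pleural effusion", "Respiratory, thoracic and mediastinal disorders"),
    ("Oedema peripheral", "General disorders and administration site conditions"),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders"),
    ("Myalgia", "Musculoskeletal and connective tissue disorders"),
    ("Insomnia", "Psychiatric disorders"),
    ("Constipation", "Gastrointestinal disorders"),
    ("Abdominal pain", "Gastrointestinal disorders"),
    ("Renal disorder", "Renal and urinary disorders"),
    ("Hypertension", "Vascular disorders"),
)

#: demographic marginals of the cohort (report shares; "missing" is a category)
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"M": 0.487, "F": 0.105, "missing": 0.408},
    "age_group": {"<18": 0.021, "18-64": 0.134, "65-79": 0.341,
                  ">=80": 0.144, "missing": 0.360},
    "occupation": {"MD": 0.917, "PH": 0.024, "OT": 0.032, "CN": 0.010,
                   "missing": 0.017},
    "country": {"Japan": 0.713, "United States": 0.091, "France": 0.053,
                "China": 0.017, "Canada": 0.015, "other": 0.111},
    "year": {"2020": 0.073, "2021": 0.003, "2022": 0.004, "2023": 0.235,
             "2024": 0.685},
}

OTHER_COUNTRIES = ("Germany", "Italy", "Spain", "United Kingdom",
                   "Korea, Republic of")

#: per-PT Weibull onset-time models (shape β, scale days)
DEFAULT_TTO_MODELS: dict[str, tuple[float, float]] = {
    "Immune-mediated enterocolitis": (0.41, 30.0),
    "Drug-induced liver injury": (1.32, 45.0),
    "Liver disorder": (1.97, 60.0),
}
#: shared onset model for every other PT; Weibull(1, 36) has median
#: 36·ln2 ≈ 25 days
DEFAULT_BASE_TTO: tuple[float, float] = (1.0, 36.0)

#: fatal-outcome proportional-hazards model: log-hazard-ratio per risk PT
DEFAULT_MORTALITY_COEFS: dict[str, float] = {
    "Immune thrombocytopenia": 2.5828,
    "Immune-mediated dermatitis": 2.3273,
    "Immune-mediated enterocolitis": 1.1487,
    "Immune-mediated myocarditis": 1.8384,
    "Multiple organ dysfunction syndrome": 2.0168,
    "Myocarditis": 1.5122,
}
DEFAULT_BASELINE_HAZARD = 6.0e-4  # per day
DEFAULT_CENSOR_DAYS = 365.0

#: non-fatal serious-outcome marginal (drawn for reports the hazard model
#: leaves alive); "none" leaves the OUTC table without a row for the report
NONFATAL_OUTCOME_P = {"HO": 0.270, "LT": 0.105, "OT": 0.246, "DS": 0.001,
                      "none": 0.114}

BACKGROUND_DRUGS = tuple(f"DRUG_{i:02d}" for i in range(1, 31))

DURVALUMAB_NAMES = ("IMFINZI", "DURVALUMAB", "Imfinzi.")
TREMELIMUMAB_NAMES = ("IMJUDO", "TREMELIMUMAB", "Imjudo.")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic FAERS draw."""

    n_background_reports: int = 20_000
    n_cohort_reports: int = 715
    planted_signals: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED))
    noise_pts: tuple[tuple[str, str], ...] = DEFAULT_NOISE_PTS
    demographics: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()})
    tto_models: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TTO_MODELS))
    base_tto: tuple[float, float] = DEFAULT_BASE_TTO
    mortality_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MORTALITY_COEFS))
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD
    censor_days: float = DEFAULT_CENSOR_DAYS
    duplicate_rate: float = 0.1
    event_dt_missing_rate: float = 0.45
    start_dt_missing_rate: float = 0.50
    event_month_precision_rate: float = 0.10
    mean_extra_pts: float = 1.2  # PTs per report = 1 + min(4, Poisson(this))
    seed: int = 0

    @property
    def pt_vocabulary(self) -> list[tuple[str, str]]:
        return [(pt, soc) for pt, (soc, _, _) in self.planted_signals.items()] + \
            list(self.noise_pts)

    def validate(self) -> None:
        for block, marg in self.demographics.items():
            total = sum(marg.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"demographic marginal {block!r} sums to {total}")
        for pt, (_, lam, share) in self.planted_signals.items():
            if lam < 1:
                raise ValueError(f"planted λ for {pt!r} must be ≥ 1")
            if share <= 0:
                raise ValueError(f"planted share for {pt!r} must be > 0")
        for pt, (shape, scale) in self.tto_models.items():
            if shape <= 0 or scale <= 0:
                raise ValueError(f"Weibull parameters for {pt!r} must be > 0")
        planted_mass = sum(s for _, _, s in self.planted_signals.values())
        if planted_mass >= 1.0:
            raise ValueError(
                f"planted reporting ratios push total PT mass to {planted_mass:.3f} ≥ 1"
            )


@dataclass
class TruthLedger:
    """Every planted quantity of one generated dataset (for tests only)."""

    planted_lambda: dict[str, float]
    planted_cohort_share: dict[str, float]
    tto_models: dict[str, tuple[float, float]]
    base_tto: tuple[float, float]
    mortality_coefs: dict[str, float]
    baseline_hazard: float
    censor_days: float
    cohort_size: int
    background_size: int
    n_duplicates: int
    cohort_caseids: list[str]
    tto_assignment: dict[str, str]
    n_tto_cases: int
    n_tto_records: int
    n_fatal: int
    seed: int

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def load(cls, path: Path | str) -> "TruthLedger":
        data = json.loads(Path(path).read_text())
        data["tto_models"] = {k: tuple(v) for k, v in data["tto_models"].items()}
        data["base_tto"] = tuple(data["base_tto"])
        return cls(**data)


# ---------------------------------------------------------------------------


def _draw_categorical(rng: np.random.Generator, marginal: dict[str, float],
                      n: int) -> np.ndarray:
    cats = list(marginal)
    p = np.array([marginal[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(cats, dtype=object), size=n, p=p)


def _ages_from_groups(rng: np.random.Generator, groups: np.ndarray) -> np.ndarray:
    lo = {"<18": 1, "18-64": 18, "65-79": 65, ">=80": 80}
    hi = {"<18": 17, "18-64": 64, "65-79": 79, ">=80": 95}
    ages = np.full(len(groups), np.nan)
    for g in lo:
        mask = groups == g
        if mask.any():
            ages[mask] = rng.integers(lo[g], hi[g] + 1, size=int(mask.sum()))
    return ages


def _dates_from_years(rng: np.random.Generator, years: np.ndarray) -> np.ndarray:
    """Random day-precision dates within each report's year, as datetime64[D]."""
    base = (years.astype(int) - 1970).astype("datetime64[Y]").astype("datetime64[D]")
    return base + rng.integers(0, 330, size=len(years)).astype("timedelta64[D]")


def _fmt_dates(dates: np.ndarray, missing: np.ndarray,
               month_only: np.ndarray | None = None) -> list[str]:
    out = []
    for i, d in enumerate(dates):
        if missing[i] or np.isnat(d):
            out.append("")
            continue
        s = pd.Timestamp(d).strftime("%Y%m%d")
        if month_only is not None and month_only[i]:
            s = s[:6]
        out.append(s)
    return out


def _pt_counts(rng: np.random.Generator, n: int, mean_extra: float) -> np.ndarray:
    return 1 + np.minimum(4, rng.poisson(mean_extra, size=n))


def generate(config: SyntheticConfig | None = None,
             seed: int | None = None) -> tuple[RawTables, TruthLedger]:
    """Generate one synthetic FAERS dataset plus its truth ledger.

    ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SyntheticConfig()
    config.validate()
    if seed is not None:
        config = SyntheticConfig(**{**asdict(config), "seed": seed})
        config.planted_signals = {k: tuple(v) if not isinstance(v, tuple) else v
                                  for k, v in config.planted_signals.items()}
        config.tto_models = {k: tuple(v) for k, v in config.tto_models.items()}
    rng = np.random.default_rng(config.seed)

    vocab = config.pt_vocabulary
    pts = np.array([pt for pt, _ in vocab], dtype=object)
    n_planted = len(config.planted_signals)

    # background per-draw PT probabilities: planted PTs get share/λ, the rest
    # of the mass goes to noise PTs on a Zipf profile
    planted_bg = np.array(
        [share / lam for _, lam, share in config.planted_signals.values()])
    noise_w = 1.0 / np.arange(1, len(config.noise_pts) + 1)
    noise_bg = (1.0 - planted_bg.sum()) * noise_w / noise_w.sum()
    p_background = np.concatenate([planted_bg, noise_bg])

    # cohort per-draw probabilities: planted mass is exactly λ·background,
    # the unplanted PTs absorb the renormalisation
    planted_cohort = np.array([share for _, _, share in config.planted_signals.values()])
    if planted_cohort.sum() >= 1.0 or np.any(planted_cohort > 1.0):
        raise ValueError("planted λ pushes PT probability mass above 1")
    noise_cohort = (1.0 - planted_cohort.sum()) * noise_bg / noise_bg.sum()
    p_cohort = np.concatenate([planted_cohort, noise_cohort])

    n_bg, n_co = config.n_background_reports, config.n_cohort_reports
    bg_caseids = np.arange(2_000_001, 2_000_001 + n_bg)
    co_caseids = np.arange(1_000_001, 1_000_001 + n_co)

    # ---- shared demographics -------------------------------------------
    n_all = n_bg + n_co
    sex = _draw_categorical(rng, config.demographics["sex"], n_all)
    age_grp = _draw_categorical(rng, config.demographics["age_group"], n_all)
    ages = _ages_from_groups(rng, age_grp)
    occ = _draw_categorical(rng, config.demographics["occupation"], n_all)
    country = _draw_categorical(rng, config.demographics["country"], n_all)
    other_mask = country == "other"
    country[other_mask] = rng.choice(np.array(OTHER_COUNTRIES, dtype=object),
                                     size=int(other_mask.sum()))
    years = _draw_categorical(rng, config.demographics["year"], n_all).astype(int)
    start_dates = _dates_from_years(rng, years)

    # ---- PT draws -------------------------------------------------------
    k_bg = _pt_counts(rng, n_bg, config.mean_extra_pts)
    flat_bg = rng.choice(len(pts), size=int(k_bg.sum()), p=p_background)
    k_co = _pt_counts(rng, n_co, config.mean_extra_pts)
    flat_co = rng.choice(len(pts), size=int(k_co.sum()), p=p_cohort)

    bg_reac = pd.DataFrame({
        "caseid": np.repeat(bg_caseids, k_bg),
        "pt_idx": flat_bg,
    }).drop_duplicates()
    co_reac = pd.DataFrame({
        "caseid": np.repeat(co_caseids, k_co),
        "pt_idx": flat_co,
    }).drop_duplicates()

    # ---- cohort onset times --------------------------------------------
    # onset model per report: first planted TTO-model PT present, else base
    pt_index = {pt: i for i, pt in enumerate(pts)}
    shape = np.full(n_co, config.base_tto[0])
    scale = np.full(n_co, config.base_tto[1])
    tto_assignment = np.full(n_co, "base", dtype=object)
    co_has = co_reac.groupby("caseid")["pt_idx"].agg(set)
    has_sets = co_has.reindex(co_caseids).to_numpy()
    for pt, (b, s) in config.tto_models.items():
        idx = pt_index.get(pt)
        if idx is None:
            continue
        # assign in declaration order; a report keeps the first matching model
        sel = np.array([idx in hs and tto_assignment[j] == "base"
                        for j, hs in enumerate(has_sets)])
        shape[sel], scale[sel] = b, s
        tto_assignment[sel] = pt
    tto_days = scale * rng.weibull(shape, size=n_co)
    tto_days_int = np.maximum(0, np.rint(tto_days)).astype(int)

    # ---- mortality ------------------------------------------------------
    risk_idx = {pt: pt_index[pt] for pt in config.mortality_coefs if pt in pt_index}
    eta = np.zeros(n_co)
    for pt, beta in config.mortality_coefs.items():
        idx = risk_idx.get(pt)
        if idx is None:
            continue
        eta += beta * np.array([idx in hs for hs in has_sets])
    hazard = config.baseline_hazard * np.exp(eta)
    death_time = rng.exponential(1.0 / hazard)
    fatal = death_time <= config.censor_days
    death_days = np.maximum(1, np.rint(death_time)).astype(int)

    co_event_days = np.where(fatal, death_days, tto_days_int)
    co_event_dates = start_dates[n_bg:] + co_event_days.astype("timedelta64[D]")

    # background event dates: base onset model (no THER rows are emitted for
    # background reports, so these never enter a TTO analysis)
    bg_tto = config.base_tto[1] * rng.weibull(config.base_tto[0], size=n_bg)
    bg_event_dates = start_dates[:n_bg] + np.rint(bg_tto).astype(int).astype(
        "timedelta64[D]")

    # ---- missingness ----------------------------------------------------
    ev_missing = rng.random(n_all) < config.event_dt_missing_rate
    st_missing = rng.random(n_all) < config.start_dt_missing_rate
    ev_month = rng.random(n_all) < config.event_month_precision_rate

    event_dates = np.concatenate([bg_event_dates, co_event_dates])
    fda_dates = event_dates + rng.integers(3, 45, size=n_all).astype("timedelta64[D]")

    caseids = np.concatenate([bg_caseids, co_caseids])
    primaryids = caseids * 100 + 2

    event_dt = _fmt_dates(event_dates, ev_missing, ev_month)
    fda_dt = _fmt_dates(fda_dates, np.zeros(n_all, bool))
    start_dt = _fmt_dates(start_dates, st_missing)

    age_str = ["" if np.isnan(a) else str(int(a)) for a in ages]
    demo = pd.DataFrame({
        "PRIMARYID": primaryids.astype(str),
        "CASEID": caseids.astype(str),
        "FDA_DT": fda_dt,
        "EVENT_DT": event_dt,
        "SEX": np.where(sex == "missing", "", sex),
        "AGE": age_str,
        "AGE_COD": ["" if np.isnan(a) else "YR" for a in ages],
        "OCCP_COD": np.where(occ == "missing", "", occ),
        "REPORTER_COUNTRY": country,
    })

    # ---- DRUG / THER / INDI --------------------------------------------
    bg_drug_w = 1.0 / np.arange(1, len(BACKGROUND_DRUGS) + 1)
    bg_drugnames = rng.choice(np.array(BACKGROUND_DRUGS, dtype=object),
                              size=n_bg, p=bg_drug_w / bg_drug_w.sum())
    # ~2% of background reports carry one (only one) of the target agents
    solo = rng.random(n_bg) < 0.02
    solo_pick = rng.random(n_bg) < 0.5
    bg_drugnames = np.where(solo & solo_pick, "DURVALUMAB",
                            np.where(solo & ~solo_pick, "TREMELIMUMAB",
                                     bg_drugnames))
    drug_rows = [pd.DataFrame({
        "PRIMARYID": primaryids[:n_bg].astype(str),
        "CASEID": bg_caseids.astype(str),
        "DRUG_SEQ": "1",
        "ROLE_COD": "PS",
        "DRUGNAME": bg_drugnames,
        "PROD_AI": bg_drugnames,
    })]
    co_roles = np.where(rng.random(n_co) < 0.8, "PS", "SS")
    for seq, name_pool, generic in ((1, DURVALUMAB_NAMES, "DURVALUMAB"),
                                    (2, TREMELIMUMAB_NAMES, "TREMELIMUMAB")):
        drug_rows.append(pd.DataFrame({
            "PRIMARYID": primaryids[n_bg:].astype(str),
            "CASEID": co_caseids.astype(str),
            "DRUG_SEQ": str(seq),
            "ROLE_COD": co_roles if seq == 1 else np.full(n_co, "PS", object),
            "DRUGNAME": rng.choice(np.array(name_pool, dtype=object), size=n_co),
            "PROD_AI": generic,
        }))
    drug = pd.concat(drug_rows, ignore_index=True)

    ther = pd.concat([
        pd.DataFrame({
            "PRIMARYID": primaryids[n_bg:].astype(str),
            "CASEID": co_caseids.astype(str),
            "DSG_DRUG_SEQ": str(seq),
            "START_DT": _fmt_dates(start_dates[n_bg:], st_missing[n_bg:]),
        })
        for seq in (1, 2)
    ], ignore_index=True)

    bg_indis = rng.choice(np.array(
        ["Non-small cell lung cancer", "Breast cancer", "Colorectal cancer",
         "Gastric cancer", "Melanoma", "Hepatocellular carcinoma"],
        dtype=object), size=n_bg, p=[0.28, 0.22, 0.2, 0.15, 0.13, 0.02])
    indi = pd.concat([
        pd.DataFrame({
            "PRIMARYID": primaryids[:n_bg].astype(str),
            "CASEID": bg_caseids.astype(str),
            "INDI_DRUG_SEQ": "1",
            "INDI_PT": bg_indis,
        }),
        pd.DataFrame({
            "PRIMARYID": np.repeat(primaryids[n_bg:].astype(str), 2),
            "CASEID": np.repeat(co_caseids.astype(str), 2),
            "INDI_DRUG_SEQ": np.tile(["1", "2"], n_co),
            "INDI_PT": "Hepatocellular carcinoma",
        }),
    ], ignore_index=True)

    # ---- REAC / OUTC ----------------------------------------------------
    reac_all = pd.concat([bg_reac, co_reac], ignore_index=True)
    reac = pd.DataFrame({
        "PRIMARYID": (reac_all["caseid"].to_numpy() * 100 + 2).astype(str),
        "CASEID": reac_all["caseid"].astype(str),
        "PT": pts[reac_all["pt_idx"].to_numpy()],
    })

    nf_categories = list(NONFATAL_OUTCOME_P)
    nf_p = np.array([NONFATAL_OUTCOME_P[c] for c in nf_categories])
    nf_draw = rng.choice(np.array(nf_categories, dtype=object), size=n_all,
                         p=nf_p / nf_p.sum())
    outc_cod = np.where(np.concatenate([np.zeros(n_bg, bool), fatal]),
                        "DE", nf_draw)
    has_outc = outc_cod != "none"
    outc = pd.DataFrame({
        "PRIMARYID": primaryids[has_outc].astype(str),
        "CASEID": caseids[has_outc].astype(str),
        "OUTC_COD": outc_cod[has_outc],
    })

    rpsr = pd.DataFrame({
        "PRIMARYID": primaryids.astype(str),
        "CASEID": caseids.astype(str),
        "RPSR_COD": "HP",
    })

    # ---- duplicates -----------------------------------------------------
    dup_mask = rng.random(n_all) < config.duplicate_rate
    n_dup = int(dup_mask.sum())
    if n_dup:
        dup_case = caseids[dup_mask]
        dup_pid = (dup_case * 100 + 1).astype(str)
        dup_fda = fda_dates[dup_mask] - rng.integers(
            1, 90, size=n_dup).astype("timedelta64[D]")
        dup_demo = demo.loc[dup_mask].copy()
        dup_demo["PRIMARYID"] = dup_pid
        dup_demo["FDA_DT"] = _fmt_dates(dup_fda, np.zeros(n_dup, bool))
        demo = pd.concat([demo, dup_demo], ignore_index=True)

        def _dup_children(df: pd.DataFrame) -> pd.DataFrame:
            child = df[df["CASEID"].isin(set(dup_case.astype(str)))].copy()
            child["PRIMARYID"] = (
                child["CASEID"].astype(np.int64) * 100 + 1).astype(str)
            return pd.concat([df, child], ignore_index=True)

        drug, reac, outc, rpsr, ther, indi = (
            _dup_children(t) for t in (drug, reac, outc, rpsr, ther, indi))

    raw = RawTables(demo=demo, drug=drug, reac=reac, outc=outc, rpsr=rpsr,
                    ther=ther, indi=indi)

    co_ev_missing = ev_missing[n_bg:]
    co_st_missing = st_missing[n_bg:]
    co_ev_month = ev_month[n_bg:]
    usable = ~co_ev_missing & ~co_st_missing & ~co_ev_month
    n_pts_per_case = co_reac.groupby("caseid").size().reindex(
        co_caseids).to_numpy()
    ledger = TruthLedger(
        planted_lambda={pt: lam for pt, (_, lam, _) in
                        config.planted_signals.items()},
        planted_cohort_share={pt: share for pt, (_, _, share) in
                              config.planted_signals.items()},
        tto_models=dict(config.tto_models),
        base_tto=tuple(config.base_tto),
        mortality_coefs=dict(config.mortality_coefs),
        baseline_hazard=config.baseline_hazard,
        censor_days=config.censor_days,
        cohort_size=n_co,
        background_size=n_bg,
        n_duplicates=n_dup,
        cohort_caseids=[str(c) for c in co_caseids],
        tto_assignment={str(c): str(m) for c, m in
                        zip(co_caseids, tto_assignment)},
        n_tto_cases=int(usable.sum()),
        n_tto_records=int(n_pts_per_case[usable].sum()),
        n_fatal=int(fatal.sum()),
        seed=config.seed,
    )
    return raw, ledger


def mortality_sim_config(n_cohort: int = 700, seed: int = 0) -> SyntheticConfig:
    """Study conditions for the mortality-factor identifiability experiment.

    Complete-case data (no missing dates, sex or age), no background reports
    or duplicates, and the six risk-factor PTs boosted to ≈6–7% report
    prevalence each so that a cohort of ~700 yields ≈200 fatal events — the
    regime in which penalised selection of all six factors is assessable.
    """
    planted = dict(DEFAULT_PLANTED)
    for pt in DEFAULT_MORTALITY_COEFS:
        soc, lam, _ = planted[pt]
        planted[pt] = (soc, lam, 0.03)
    demographics = {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()}
    demographics["sex"] = {"M": 0.55, "F": 0.45}
    demographics["age_group"] = {"<18": 0.02, "18-64": 0.25, "65-79": 0.55,
                                 ">=80": 0.18}
    return SyntheticConfig(
        n_background_reports=0,
        n_cohort_reports=n_cohort,
        planted_signals=planted,
        demographics=demographics,
        baseline_hazard=4.0e-4,
        duplicate_rate=0.0,
        event_dt_missing_rate=0.0,
        start_dt_missing_rate=0.0,
        event_month_precision_rate=0.0,
        seed=seed,
    )


def simulate_to_dir(config: SyntheticConfig, out_dir: Path | str,
                    seed: int | None = None) -> tuple[dict, Path]:
    """Generate and write FAERS ASCII tables plus ``truth.json``."""
    raw, ledger = generate(config, seed=seed)
    out_dir = Path(out_dir)
    written = write_quarter(raw, out_dir)
    truth_path = out_dir / "truth.json"
    ledger.save(truth_path)
    return written, truth_path
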