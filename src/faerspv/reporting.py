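"""Publication-style outputs and the end-to-end pipeline driver.

Renders the demographics table (counts and one-decimal percentages), the
signal table (``"ROR (lo-hi)"`` formatting, two decimals), volcano-plot data
(log ROR vs −log10 adjusted p) and a run manifest with per-stage row counts,
and wires ingest → signals → tto → risk model together under one
:class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ingest import (CaseSet, DemographicsTable, deduplicate, filter_indication,
                     match_drug, read_quarter, summarize_demographics)
from .mortality import build_design_matrix, fit_risk_model
from .signals import SignalRecord, SignalThresholds, records_to_frame, screen
from .tto import compute_tto, fit_per_pt, km_curve, tto_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    quarter_dirs: list[str] = field(default_factory=list)
    drug_groups: list[list[str]] = field(default_factory=lambda: [
        ["durvalumab", "imfinzi"], ["tremelimumab", "imjudo"]])
    indication: str = "hepatocellular carcinoma"
    ps_only: bool = False
    ime_list: str | None = None
    dme_list: str | None = None
    label_terms: str | None = None
    pt_soc_map: str | None = None
    thresholds: dict = field(default_factory=dict)
    ic_method: str = "noren"
    folds: int = 10
    horizons: list[float] = field(default_factory=lambda: [30.0, 60.0, 90.0])
    min_pt_cases: int = 2
    seed: int = 0
    out_dir: str = "pv_out"

    @classmethod
    def from_toml(cls, path: Path | str) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _read_term_list(path: str | None) -> list[str] | None:
    if path is None:
        return None
    p = Path(path)
    if not p.exists():
        logger.warning("term list %s missing; flags omitted", path)
        return None
    terms = [line.split("\t")[0].strip() for line in p.read_text().splitlines()]
    return [t for t in terms if t]


def render_table1(demographics: DemographicsTable) -> pd.DataFrame:
    """Demographics as (block, category, n, percent) with one-decimal
    percentages; empty cohorts give a header-only table."""
    df = demographics.table.copy()
    if len(df) and demographics.n_reports == 0:
        df = df.iloc[0:0]
    df["percent"] = df["percent"].round(1)
    return df


def _fmt_ci(mid: float, lo: float, hi: float) -> str:
    if any(np.isnan(v) for v in (mid, lo, hi)):
        return "NA"
    return f"{mid:.2f} ({lo:.2f}-{hi:.2f})"


def render_signal_table(records: Sequence[SignalRecord], top_k: int = 20,
                        rank_by: str = "case") -> pd.DataFrame:
    """Top-k signal table with ``"estimate (lo-hi)"`` formatting.

    ``rank_by="case"`` sorts by descending case count (signal-table style),
    ``rank_by="ror"`` by descending ROR (forest-plot style); ties break by
    PT name, and the sort is stable.
    """
    recs = [r for r in records if r.consensus]
    key = (lambda r: (-r.a, r.pt)) if rank_by == "case" else (
        lambda r: (-(r.ror if not np.isnan(r.ror) else -np.inf), r.pt))
    recs = sorted(recs, key=key)[:top_k]
    rows = []
    for r in recs:
        rows.append({
            "pt": r.pt,
            "soc": r.soc,
            "case_n": r.a,
            "ror_ci": _fmt_ci(r.ror, r.ror_lo, r.ror_hi),
            "prr_ci": _fmt_ci(r.prr, r.prr_lo, r.prr_hi),
            "chi2": round(r.chi2, 2) if not np.isnan(r.chi2) else np.nan,
            "ic_ic025": f"{r.ic:.2f} ({r.ic025:.2f})",
            "ebgm_ebgm05": f"{r.ebgm:.2f} ({r.ebgm05:.2f})",
            "flags": "|".join(sorted(r.flags)),
        })
    return pd.DataFrame(rows, columns=["pt", "soc", "case_n", "ror_ci",
                                       "prr_ci", "chi2", "ic_ic025",
                                       "ebgm_ebgm05", "flags"])


def volcano_data(signal_frame: pd.DataFrame) -> pd.DataFrame:
    """log ROR vs −log10 Bonferroni-adjusted p, with case counts."""
    df = signal_frame
    with np.errstate(divide="ignore"):
        return pd.DataFrame({
            "pt": df["pt"],
            "log_ror": np.log(df["ror"]),
            "neg_log10_p_adj": -np.log10(df["p_adj"].clip(lower=1e-300)),
            "case_n": df["a"],
            "consensus": df["consensus"],
        })


def _write_with_hash(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_all(config: RunConfig, raw=None) -> dict:
    """Execute the full pipeline and write every artefact to ``out_dir``.

    ``raw`` may carry pre-loaded :class:`RawTables` (e.g. fresh from the
    generator); otherwise tables are read from ``config.quarter_dirs``.
    Returns the manifest (also written as ``manifest.json``), whose
    ``counts`` mirror the flow: raw reports → deduplicated → drug-matched →
    indication cohort → signals → TTO records → risk-model records.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config_hash": cfg_hash, "counts": {}, "stages": []}

    def _stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        _stage("ingest")
        if raw is None:
            from .ingest import concat_quarters
            quarters = []
            for qdir in config.quarter_dirs:
                qdir = Path(qdir)
                paths = {name: qdir / f"{name.upper()}.txt"
                         for name in ("demo", "drug", "reac", "outc", "rpsr",
                                      "ther", "indi")}
                quarters.append(read_quarter(paths))
            raw = concat_quarters(quarters)
        manifest["counts"]["raw_reports"] = len(raw.demo)
        universe = deduplicate(raw)
        manifest["counts"]["deduplicated"] = len(universe)
        roles = ("PS",) if config.ps_only else ("PS", "SS", "C", "I")
        matched = match_drug(universe, config.drug_groups, roles=roles)
        manifest["counts"]["drug_matched"] = len(matched)
        cohort = filter_indication(matched, config.indication)
        manifest["counts"]["cohort"] = len(cohort)

        demo = summarize_demographics(cohort)
        _write_with_hash(render_table1(demo), out / "table1.csv", cfg_hash)

        _stage("signals")
        flat_patterns = [p for g in config.drug_groups for p in g]
        pt_soc = {}
        if config.pt_soc_map and Path(config.pt_soc_map).exists():
            m = pd.read_csv(config.pt_soc_map, sep="\t")
            pt_soc = dict(zip(m.iloc[:, 0], m.iloc[:, 1]))
        records, prior = screen(
            cohort, universe, pt_soc=pt_soc,
            thresholds=SignalThresholds(**config.thresholds),
            ic_method=config.ic_method,
            ime_list=_read_term_list(config.ime_list),
            dme_list=_read_term_list(config.dme_list),
            label_terms=_read_term_list(config.label_terms),
        )
        sig = records_to_frame(records)
        _write_with_hash(sig, out / "signals.csv", cfg_hash)
        _write_with_hash(render_signal_table(records, rank_by="case"),
                         out / "table2.csv", cfg_hash)
        _write_with_hash(render_signal_table(records, rank_by="ror"),
                         out / "forest_top20.csv", cfg_hash)
        _write_with_hash(volcano_data(sig), out / "volcano.csv", cfg_hash)
        positive = sorted(sig.loc[sig["consensus"], "pt"])
        manifest["counts"]["pts_tested"] = len(sig)
        manifest["counts"]["consensus_signals"] = len(positive)

        _stage("tto")
        tto = compute_tto(cohort, drug_patterns=flat_patterns)
        manifest["counts"]["tto_records"] = len(tto)
        manifest["counts"]["tto_cases"] = int(tto["caseid"].nunique()) if len(tto) else 0
        if len(tto):
            summ = tto_summary(tto["tto_days"])
            _write_with_hash(summ["bins"], out / "tto_bins.csv", cfg_hash)
            tto = tto.assign(pt_positive=tto["pt"].isin(positive))
            first = tto.sort_values("tto_days").drop_duplicates("caseid")
            km_all = km_curve(first)
            parts = [km_all["curves"].assign(strata="overall", logrank_p=np.nan)]
            for factor in ("sex", "age_group", "pt_positive"):
                res = km_curve(first, strata=factor)
                parts.append(res["curves"].assign(strata=factor,
                                                  logrank_p=res["logrank_p"]))
            _write_with_hash(pd.concat(parts, ignore_index=True),
                             out / "km_curves.csv", cfg_hash)
            top_pts = (tto["pt"].value_counts().head(3).index.tolist())
            _write_with_hash(fit_per_pt(tto, pts=sorted(set(top_pts))),
                             out / "weibull_fits.csv", cfg_hash)
            manifest["counts"]["tto_median_days"] = float(summ["median"])

        _stage("riskmodel")
        risk_summary: dict = {"status": "skipped"}
        try:
            design = build_design_matrix(cohort, positive,
                                         drug_patterns=flat_patterns,
                                         min_pt_cases=config.min_pt_cases)
            fit = fit_risk_model(design, folds=config.folds, seed=config.seed,
                                 horizons=tuple(config.horizons))
            manifest["counts"]["risk_records"] = fit.n_records
            manifest["counts"]["risk_events"] = fit.n_events
            risk_summary = {
                "status": "ok",
                "selected": fit.lasso.selected,
                "alpha_min": fit.lasso.alpha_min,
                "coefficients": fit.coefficients,
                "logrank_p": (fit.stratification.logrank_p
                              if fit.stratification else None),
                "auc": (fit.roc.set_index("horizon")["auc"].to_dict()
                        if fit.roc is not None else {}),
            }
            if fit.cox is not None:
                _write_with_hash(fit.cox.reset_index(names="variable"),
                                 out / "cox_table.csv", cfg_hash)
            if fit.roc is not None:
                _write_with_hash(fit.roc, out / "roc_auc.csv", cfg_hash)
            if fit.stratification is not None:
                _write_with_hash(fit.stratification.km_curves,
                                 out / "risk_km.csv", cfg_hash)
        except ValueError as exc:
            logger.warning("risk model skipped: %s", exc)
            risk_summary = {"status": f"skipped: {exc}"}
        (out / "riskmodel.json").write_text(json.dumps(risk_summary, indent=1))
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
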