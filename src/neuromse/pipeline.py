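"""Orchestration: clean -> summarize -> entropy -> prognostics over a cohort.

A cohort directory holds ``clinical.csv`` plus, per patient, either a raw
waveform recording (``<patient_id>.h5``) or a precomputed 10-s series
(``<patient_id>_series.csv``) and optionally manual artifact annotations
(``<patient_id>_annotations.csv``).  The pipeline writes per-patient MSE
curves, a univariable ROC table, a multivariable model/validation table, an
ordinal-analysis table, cleaning reports, an exclusion list with reasons,
and a manifest recording configuration and seeds.

The early-prediction secondary analysis is a window mode, not a separate
code path: ``first_48h_from_admission`` restricts every channel to windows
starting within 48 h of monitoring onset before entropy is computed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import prognostics as prog
from .cleaning import CleaningConfig, clean_signal, report_frame
from .entropy import EntropyConfig, mse_curve, mse_stability
from .io import (
    PatientRecord,
    clinical_frame,
    read_annotations,
    read_clinical_table,
    read_waveform,
)
from .summarize import TEN_SECOND_CHANNELS, TenSecondSeries, summarize_patient

logger = logging.getLogger(__name__)

WINDOW_MODES = ("full_stay", "first_48h_from_admission")


@dataclass
class PipelineConfig:
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    window_mode: str = "full_stay"
    covariates: tuple[str, ...] = prog.DEFAULT_COVARIATES
    bootstrap_B: int = 1000
    internal_validation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_mode not in WINDOW_MODES:
            raise ValueError(f"window_mode must be one of {WINDOW_MODES}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "cleaning" in raw:
            kwargs["cleaning"] = CleaningConfig(**raw["cleaning"])
        if "entropy" in raw:
            ent = dict(raw["entropy"])
            if "scales" in ent:
                ent["scales"] = tuple(ent["scales"])
            kwargs["entropy"] = EntropyConfig(**ent)
        for key in ("window_mode", "bootstrap_B", "internal_validation", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "covariates" in raw:
            kwargs["covariates"] = tuple(raw["covariates"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["entropy"]["scales"] = list(self.entropy.scales)
        d["cleaning"]["cardiac_band"] = list(self.cleaning.cardiac_band)
        d["covariates"] = list(self.covariates)
        return d


# ---------------------------------------------------------------------------
# cohort loading


def load_cohort(cohort_dir) -> tuple[list[PatientRecord], dict]:
    """Read the clinical table and locate each patient's signal source."""
    cohort_dir = Path(cohort_dir)
    records = read_clinical_table(cohort_dir / "clinical.csv")
    sources = {}
    for rec in records:
        h5 = cohort_dir / f"{rec.patient_id}.h5"
        csv = cohort_dir / f"{rec.patient_id}_series.csv"
        ann = cohort_dir / f"{rec.patient_id}_annotations.csv"
        if h5.exists():
            sources[rec.patient_id] = {"kind": "waveform", "path": h5,
                                       "annotations": ann if ann.exists() else None}
        elif csv.exists():
            sources[rec.patient_id] = {"kind": "series", "path": csv}
    return records, sources


def _patient_series(rec: PatientRecord, source, config: PipelineConfig):
    """Clean and summarize one patient; returns (series, cleaning reports)."""
    if source["kind"] == "series":
        return TenSecondSeries.read_csv(rec.patient_id, source["path"]), []
    annotations = (
        read_annotations(source["annotations"]) if source.get("annotations") else []
    )
    signals = {}
    reports = []
    for channel in ("ABP", "ICP", "HR"):
        try:
            sig = read_waveform(source["path"], channel)
        except KeyError:
            continue
        cleaned, report = clean_signal(sig, config.cleaning, annotations)
        signals[channel] = cleaned
        reports.append(report)
    series = summarize_patient(
        rec.patient_id,
        abp=signals.get("ABP"),
        icp=signals.get("ICP"),
        hr=signals.get("HR"),
        cardiac_band=config.cleaning.cardiac_band,
        min_valid_fraction=config.cleaning.min_window_valid_fraction,
    )
    return series, reports


def _apply_window_mode(series: TenSecondSeries, rec: PatientRecord,
                       config: PipelineConfig) -> TenSecondSeries:
    if config.window_mode == "full_stay":
        return series
    limit = rec.monitoring_start + 48 * 3600.0
    keep = series.window_start_times < limit
    channels = {c: np.where(keep, v, np.nan) for c, v in series.channels.items()}
    return TenSecondSeries(series.patient_id, series.window_start_times, channels)


# ---------------------------------------------------------------------------
# stage outputs


def compute_mse_table(series_by_patient: dict, records, config: PipelineConfig):
    """Per-patient, per-channel MSE curves as a tidy table.

    Returns ``(table, exclusions)``; patients with no channel yielding a
    defined MSE area are listed in ``exclusions`` with a reason.
    """
    by_id = {r.patient_id: r for r in records}
    rows = []
    exclusions = []
    for pid, series in series_by_patient.items():
        rec = by_id.get(pid)
        if rec is None:
            continue
        series = _apply_window_mode(series, rec, config)
        any_defined = False
        for channel in TEN_SECOND_CHANNELS:
            if channel not in series.channels:
                continue
            res = mse_curve(series.channels[channel], config.entropy, channel)
            row = {"patient_id": pid, "channel": channel}
            for s, v in zip(res.scales, res.values):
                row[f"scale_{s}"] = v
            row.update(
                auc=res.auc, n_windows_used=res.n_windows_used, r_used=res.r_used
            )
            rows.append(row)
            if np.isfinite(res.auc):
                any_defined = True
        if not any_defined:
            exclusions.append(
                {"patient_id": pid, "reason": "no channel with defined MSE"}
            )
    table = pd.DataFrame(rows)
    return table, pd.DataFrame(exclusions, columns=["patient_id", "reason"])


def mse_wide(mse_table: pd.DataFrame) -> pd.DataFrame:
    """MSE area per patient as one column per channel."""
    return mse_table.pivot(index="patient_id", columns="channel", values="auc")


def analyze(mse_table: pd.DataFrame, records, config: PipelineConfig):
    """The full statistical battery on computed MSE areas.

    Available-case per metric: each channel's analyses use the patients for
    whom that channel (and covariates) are defined.  Returns a dict of
    tables: ``roc`` (univariable), ``models`` (adjusted logistic with
    optional internal validation), ``ordinal`` (proportional odds + sliding
    dichotomy).
    """
    wide = mse_wide(mse_table)
    clin = clinical_frame(records)
    df = clin.join(wide, how="inner")
    y_all = prog.unfavorable(df["gose"])
    roc_rows, model_rows, ordinal_rows = [], [], []
    for channel in [c for c in TEN_SECOND_CHANNELS if c in wide.columns]:
        sub = df[np.isfinite(df[channel])]
        if len(sub) < 10:
            logger.warning("channel %s: only %d patients; skipped", channel, len(sub))
            continue
        y = prog.unfavorable(sub["gose"])
        if y.min() == y.max():
            continue
        scores = sub[channel].to_numpy(dtype=float)
        # univariable: t-test, ROC with DeLong CI, Youden operating point
        t, dof, p_t = prog.t_test(scores[y == 0], scores[y == 1])
        auc, ci = prog.roc_auc(-scores, y)  # low MSE predicts the event
        op = prog.youden_threshold(scores, y, event_low=True)
        roc_rows.append(
            {
                "channel": channel, "n": len(sub), "t": t, "t_p": p_t,
                "auc": auc, "auc_lo": ci[0], "auc_hi": ci[1],
                "threshold": op["threshold"],
                "sensitivity": op["sensitivity"], "specificity": op["specificity"],
                "ppv": op["ppv"], "npv": op["npv"], "accuracy": op["accuracy"],
            }
        )
        # multivariable: covariate-adjusted logistic regression
        X = sub[list(config.covariates) + [channel]].astype(float)
        fit = prog.logistic_fit(X, y)
        base = prog.logistic_fit(X, y, list(config.covariates))
        _, p_delong = prog.delong_compare(fit.fitted_probs, base.fitted_probs, y)
        row = {
            "channel": channel, "n": len(sub),
            "or": fit.odds_ratios.loc[channel, "OR"],
            "or_lo": fit.odds_ratios.loc[channel, "lo"],
            "or_hi": fit.odds_ratios.loc[channel, "hi"],
            "or_p": fit.odds_ratios.loc[channel, "p"],
            "auc": fit.auc, "auc_lo": fit.auc_ci[0], "auc_hi": fit.auc_ci[1],
            "r2": fit.nagelkerke_r2, "brier": fit.brier,
            "delong_p_vs_base": p_delong,
        }
        if config.internal_validation:
            val = prog.bootstrap_validate(
                X, y, B=config.bootstrap_B, seed=config.seed
            )
            row.update(
                auc_corrected=val["corrected"]["auc"],
                r2_corrected=val["corrected"]["r2"],
                brier_corrected=val["corrected"]["brier"],
            )
        model_rows.append(row)
        # ordinal: proportional odds (worse-is-higher) + sliding dichotomy
        worse = prog.ordinal_worseness(sub["gose"])
        try:
            po = prog.polr_fit(X, worse)
            brant = prog.brant_test(X, worse)
            po_row = {
                "channel": channel,
                "common_or": po.odds_ratios.loc[channel, "OR"],
                "common_or_lo": po.odds_ratios.loc[channel, "lo"],
                "common_or_hi": po.odds_ratios.loc[channel, "hi"],
                "common_or_p": po.odds_ratios.loc[channel, "p"],
                "brant_p": brant["omnibus"]["p"],
            }
        except Exception as exc:
            logger.warning("channel %s: ordinal analysis skipped (%s)", channel, exc)
            po_row = {"channel": channel}
        try:
            sd = prog.sliding_dichotomy(
                sub, sub["gose"], scores, covariates=config.covariates
            )
            po_row.update(
                sliding_or=sd["or"], sliding_or_lo=sd["ci"][0],
                sliding_or_hi=sd["ci"][1], sliding_p=sd["p"],
            )
        except Exception as exc:
            logger.warning("channel %s: sliding dichotomy skipped (%s)", channel, exc)
        ordinal_rows.append(po_row)
    return {
        "roc": pd.DataFrame(roc_rows),
        "models": pd.DataFrame(model_rows),
        "ordinal": pd.DataFrame(ordinal_rows),
        "n_unfavorable": int(y_all.sum()),
        "n_total": int(len(df)),
    }


def run_pipeline(config: PipelineConfig, cohort_dir, out_dir):
    """End-to-end run over a cohort directory; writes all result tables."""
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, sources = load_cohort(cohort_dir)
    series_by_patient = {}
    all_reports = []
    exclusions = []
    timings = {}
    for rec in records:
        src = sources.get(rec.patient_id)
        if src is None:
            exclusions.append(
                {"patient_id": rec.patient_id, "reason": "no signal data"}
            )
            continue
        series, reports = _patient_series(rec, src, config)
        series_by_patient[rec.patient_id] = series
        for rep in reports:
            for rule, count in rep.removed_per_rule.items():
                all_reports.append(
                    {"patient_id": rec.patient_id, "channel": rep.channel_label,
                     "rule": rule, "samples_removed": count}
                )
    timings["clean_summarize_s"] = round(time.time() - t0, 3)

    t1 = time.time()
    mse_table, mse_exclusions = compute_mse_table(series_by_patient, records, config)
    exclusions.extend(mse_exclusions.to_dict("records"))
    timings["entropy_s"] = round(time.time() - t1, 3)

    t2 = time.time()
    analyzed = records
    if exclusions:
        excluded_ids = {e["patient_id"] for e in exclusions}
        analyzed = [r for r in records if r.patient_id not in excluded_ids]
        for e in exclusions:
            logger.info("excluded %s: %s", e["patient_id"], e["reason"])
    tables = analyze(mse_table, analyzed, config)
    timings["analysis_s"] = round(time.time() - t2, 3)

    mse_table.to_csv(out_dir / "mse.csv", index=False)
    tables["roc"].to_csv(out_dir / "roc_table.csv", index=False)
    tables["models"].to_csv(out_dir / "model_table.csv", index=False)
    tables["ordinal"].to_csv(out_dir / "ordinal_table.csv", index=False)
    pd.DataFrame(all_reports,
                 columns=["patient_id", "channel", "rule", "samples_removed"]
                 ).to_csv(out_dir / "cleaning_report.csv", index=False)
    pd.DataFrame(exclusions, columns=["patient_id", "reason"]).to_csv(
        out_dir / "exclusions.csv", index=False
    )
    config_dict = config.to_dict()
    manifest = {
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_patients": len(records),
        "n_analyzed": tables["n_total"],
        "n_unfavorable": tables["n_unfavorable"],
        "timings": timings,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return tables


# ---------------------------------------------------------------------------
# secondary analyses


EVENT_FLAGS = ("rebleeding", "global_edema", "herniation", "seizures",
               "hydrocephalus", "vasospasm", "dci")


def run_event_comparisons(mse_table: pd.DataFrame, records,
                          channels=("SBP", "HR", "ICP")):
    """Group means and t-tests of MSE metrics against clinical event flags.

    One row per event x metric; rows with fewer than two patients in either
    group are marked not evaluable.
    """
    wide = mse_wide(mse_table)
    clin = clinical_frame(records)
    df = clin.join(wide, how="inner")
    rows = []
    for event in EVENT_FLAGS:
        if event not in df.columns or df[event].isna().all():
            continue
        flag = df[event].astype(float)
        for channel in channels:
            if channel not in df.columns:
                continue
            vals = df[channel].to_numpy(dtype=float)
            ok = np.isfinite(vals) & np.isfinite(flag)
            absent = vals[ok & (flag == 0)]
            present = vals[ok & (flag == 1)]
            row = {
                "event": event, "channel": channel,
                "n_without": len(absent), "n_with": len(present),
                "mean_without": absent.mean() if len(absent) else np.nan,
                "sd_without": absent.std(ddof=1) if len(absent) > 1 else np.nan,
                "mean_with": present.mean() if len(present) else np.nan,
                "sd_with": present.std(ddof=1) if len(present) > 1 else np.nan,
            }
            if len(absent) >= 2 and len(present) >= 2:
                t, _, p = prog.t_test(absent, present)
                row.update(t=t, p=p, evaluable=True)
            else:
                row.update(t=np.nan, p=np.nan, evaluable=False)
            rows.append(row)
    return pd.DataFrame(rows)


def run_stability_analysis(series_by_patient: dict, channel: str,
                           durations_h=tuple(range(1, 25)),
                           config: EntropyConfig | None = None):
    """Within-patient MSE convergence over growing durations, plus the
    cohort-level correlation of MSE with total recording duration.

    Returns ``(per_patient, summary)``: a tidy per-duration table with the
    absolute difference from each patient's longest-duration value, and a
    dict with the Pearson correlation between full-recording MSE and
    recording length.
    """
    config = config or EntropyConfig()
    rows = []
    full_auc, full_dur = [], []
    for pid, series in series_by_patient.items():
        values = (
            series.channels[channel]
            if isinstance(series, TenSecondSeries)
            else np.asarray(series, dtype=float)
        )
        per_dur = mse_stability(values, durations_h, config, channel)
        max_d = max(per_dur)
        ref = per_dur[max_d].auc
        for d, res in per_dur.items():
            rows.append(
                {
                    "patient_id": pid, "duration_h": d, "auc": res.auc,
                    "abs_diff_from_longest": abs(res.auc - ref)
                    if np.isfinite(res.auc) and np.isfinite(ref)
                    else np.nan,
                }
            )
        full_auc.append(mse_curve(values, config, channel).auc)
        full_dur.append(len(values) / 360.0)
    per_patient = pd.DataFrame(rows)
    full_auc = np.asarray(full_auc)
    full_dur = np.asarray(full_dur)
    ok = np.isfinite(full_auc)
    if ok.sum() >= 3 and np.std(full_dur[ok]) > 0:
        r = float(np.corrcoef(full_auc[ok], full_dur[ok])[0, 1])
    else:
        r = np.nan
    summary = {"duration_mse_correlation": r, "n": int(ok.sum())}
    return per_patient, summary
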