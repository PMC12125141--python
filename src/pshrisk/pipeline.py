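"""End-to-end orchestration: simulate -> qc -> transients -> features ->
fit -> explain, with a run manifest and deterministic seed fan-out.

Every stage writes its artifacts (documented CSV/JSON dialects) before
the next stage starts, so a failed run preserves partial outputs, and an
identical config + seed reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .features import build_feature_set, compare_groups, transient_feature_table
from .explain import (
    attribution_importance_from_report,
    importance_from_report,
    pair_importance,
    temporal_profile,
)
from .io import read_trend_csv, write_trend_csv, qc_record
from .model import ModelConfig, grid_search_cv
from .transients import METRICS, WINDOW_HOURS

__all__ = ["RunConfig", "run_pipeline", "grid_summary"]

log = logging.getLogger("pshrisk")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    n_patients: int = 41
    n_at_risk: int = 14
    level: int = 3
    metric: str = "zcr"
    window_hours: float = 3.0
    k_folds: int = 5
    max_missing_frac: float = 0.10
    stages: tuple[str, ...] = (
        "simulate", "qc", "transients", "features", "fit", "explain",
    )

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")
        if self.window_hours not in WINDOW_HOURS:
            raise ValueError(
                f"unknown window {self.window_hours!r}; choose from {WINDOW_HOURS}")
        unknown = set(self.stages) - {
            "simulate", "qc", "transients", "features", "fit", "explain"}
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    trends_dir = out / "trends"

    metadata = records = None
    if "simulate" in config.stages:
        params = synthetic.CohortParams(
            n_patients=config.n_patients,
            n_at_risk=config.n_at_risk,
            seed=config.seed,
        )
        metadata, records = synthetic.gen_cohort(params)
        trends_dir.mkdir(exist_ok=True)
        for rec in records:
            write_trend_csv(rec, trends_dir / f"{rec.patient_id}.csv")
        metadata.to_csv(out / "metadata.csv", index=False)
        manifest["stages"]["simulate"] = {"n_patients": len(records)}
        log.info("simulate: wrote %d trend records", len(records))

    if metadata is None:
        metadata = pd.read_csv(out / "metadata.csv")
    if records is None:
        records = [read_trend_csv(p) for p in sorted(trends_dir.glob("*.csv"))]

    if "qc" in config.stages:
        reports = [qc_record(r, max_missing_frac=config.max_missing_frac)
                   for r in records]
        qc_frame = pd.DataFrame([
            {
                "patient_id": r.patient_id,
                "passed": r.passed,
                "failed_channels": ";".join(r.failed_channels),
                **{f"missing_{ch}": frac for ch, frac in r.missing_fraction.items()},
            }
            for r in reports
        ])
        qc_frame.to_csv(out / "qc_report.csv", index=False)
        keep = {r.patient_id for r in reports if r.passed}
        dropped = [r.patient_id for r in reports if not r.passed]
        for pid in dropped:
            log.info("qc: excluding %s (failed channels: %s)", pid,
                     next(x.failed_channels for x in reports if x.patient_id == pid))
        records = [r for r in records if r.patient_id in keep]
        metadata = metadata[metadata["patient_id"].isin(keep)].reset_index(drop=True)
        manifest["stages"]["qc"] = {"passed": len(keep), "excluded": dropped}

    transient = None
    if "transients" in config.stages and config.level == 3:
        transient = transient_feature_table(records, config.window_hours)
        transient.to_csv(out / "features_transient.csv", index=False)
        manifest["stages"]["transients"] = {"rows": len(transient)}

    fm = None
    if "features" in config.stages:
        fm = build_feature_set(
            config.level, metadata, records=records if config.level >= 2 else None,
            transient_features=transient,
            metric=config.metric if config.level == 3 else None,
            window_hours=config.window_hours if config.level == 3 else None,
        )
        fm.X.to_csv(out / f"features_level{config.level}.csv")
        comparison = compare_groups(metadata.drop(columns=["patient_id"]))
        comparison.to_csv(out / "group_comparison.csv", index=False)
        manifest["stages"]["features"] = {
            "level": config.level,
            "n_columns": len(fm.feature_names),
        }

    report = None
    if "fit" in config.stages:
        if fm is None:
            raise RuntimeError("fit stage requires the features stage")
        report = grid_search_cv(fm, ModelConfig(k_folds=config.k_folds,
                                                seed=config.seed))
        with open(out / "cv_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        manifest["stages"]["fit"] = {
            "best_strength": report.best_strength,
            "best_weighting": report.best_weighting,
            "mean_auc": report.best.mean_auc,
            "mean_acc": report.best.mean_acc,
        }

    if "explain" in config.stages:
        if report is None or fm is None:
            raise RuntimeError("explain stage requires the fit stage")
        coef_imp = importance_from_report(report)
        attr_imp = attribution_importance_from_report(
            report, fm.X.to_numpy(dtype=float))
        imp = pd.DataFrame({
            "feature": coef_imp.feature_names,
            "coefficient": coef_imp.normalized,
            "attribution": attr_imp.normalized,
        })
        imp.to_csv(out / "importance.csv", index=False)
        stage: dict = {}
        if config.level == 3:
            prof = temporal_profile(coef_imp)
            pd.DataFrame({
                "bin_index": prof.bin_index,
                "value": prof.values,
            }).to_csv(out / "temporal_profile.csv", index=False)
            stage["influential_bins"] = prof.influential_bins
            stage["top_pairs"] = list(pair_importance(coef_imp).index[:2])
        manifest["stages"]["explain"] = stage

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def grid_summary(
    metadata: pd.DataFrame,
    records: list,
    seed: int = 0,
    metrics: tuple[str, ...] = METRICS,
    windows: tuple[float, ...] = WINDOW_HOURS,
    k_folds: int = 5,
) -> pd.DataFrame:
    """Best-model AUC/ACC per (variability metric x window) configuration.

    Enumerates the full metric-by-window design (12 configurations for
    the 3 x 4 default) and reports each configuration's grid-searched
    mean +/- sd AUC and accuracy, one row per window with one column
    block per metric, plus a long-format section.
    """
    rows = []
    for window in windows:
        transient = transient_feature_table(records, window)
        for metric in metrics:
            fm = build_feature_set(3, metadata, records=records,
                                   transient_features=transient,
                                   metric=metric, window_hours=window)
            report = grid_search_cv(fm, ModelConfig(k_folds=k_folds, seed=seed))
            rows.append({
                "window_h": window,
                "metric": metric,
                "mean_auc": report.best.mean_auc,
                "sd_auc": report.best.sd_auc,
                "mean_acc": report.best.mean_acc,
                "sd_acc": report.best.sd_acc,
                "strength": report.best_strength,
                "weighting": report.best_weighting,
            })
    return pd.DataFrame(rows)
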