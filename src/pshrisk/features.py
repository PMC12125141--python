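"""Feature-set assembly and the univariate group comparison.

Three nested predictor sets are used to model PSH risk:

* level I   — clinical metadata: age, sex, GCS, ISS, trauma type, Hb,
  WBC and six admission-CT lesion flags (13 columns);
* level II  — level I plus the 72-h means of the five neuromonitoring
  trend channels (18 columns);
* level III — level II plus one variability metric (ZCR, STD or MEAN)
  of the rolling ANS-hemodynamics correlation, for each of the six
  signal pairs and each time bin of the chosen window length.

Missing transient features (degenerate bins) are left as NaN here and
imputed fold-locally at model time to avoid cross-validation leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import TrendRecord, TREND_CHANNELS, interpolate_gaps
from .transients import (
    SIGNAL_PAIRS,
    METRICS,
    VariabilityFeature,
    rolling_correlation,
    variability_metrics,
    n_bins_for_window,
)

__all__ = [
    "FeatureMatrix",
    "LEVEL1_COLUMNS",
    "TREND_MEAN_COLUMNS",
    "transient_feature_table",
    "transient_column_name",
    "build_feature_set",
    "compare_groups",
]

LEVEL1_COLUMNS = (
    "age", "sex_male", "gcs_sum", "iss", "trauma_multiorgan", "hb", "wbc",
    "ct_sdh", "ct_edh", "ct_tich", "ct_edema", "ct_dai", "ct_tsah",
)
TREND_MEAN_COLUMNS = tuple(f"mean_{ch}" for ch in TREND_CHANNELS)


@dataclass
class FeatureMatrix:
    """Patients x named features, with labels and provenance."""

    X: pd.DataFrame                 # indexed by patient_id
    y: pd.Series                    # aligned binary labels
    level: int
    metric: str | None = None
    window_hours: float | None = None

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("features and labels must share the patient index")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def transient_column_name(pair: tuple[str, str], metric: str,
                          window_hours: float, bin_index: int) -> str:
    w = int(window_hours) if float(window_hours).is_integer() else window_hours
    return f"{metric}_{pair[0]}_{pair[1]}_w{w}_b{bin_index:02d}"


def transient_feature_table(
    records: list[TrendRecord],
    window_hours: float,
    min_valid: float = 0.9,
    interp_max_run: int = 10,
) -> pd.DataFrame:
    """Long-format variability features for all patients, pairs and metrics.

    Channels are gap-interpolated (runs of at most ``interp_max_run``
    samples) before the rolling correlation, mirroring the record-level
    preprocessing. Columns: patient_id, pair, window_h, metric,
    bin_index, bin_start_h, value.
    """
    rows = []
    for rec in records:
        filled = {
            ch: interpolate_gaps(rec.channels[ch], max_run=interp_max_run)
            for ch in TREND_CHANNELS
        }
        for pair in SIGNAL_PAIRS:
            track = rolling_correlation(
                filled[pair[0]], filled[pair[1]], window_hours, min_valid)
            for feat in variability_metrics(track):
                rows.append({
                    "patient_id": rec.patient_id,
                    "pair": f"{pair[0]}-{pair[1]}",
                    "window_h": window_hours,
                    "metric": feat.metric,
                    "bin_index": feat.bin_index,
                    "bin_start_h": feat.bin_start_hours,
                    "value": feat.value,
                })
    return pd.DataFrame(rows)


def _trend_means(records: list[TrendRecord], interp_max_run: int = 10) -> pd.DataFrame:
    rows = {}
    for rec in records:
        rows[rec.patient_id] = {
            f"mean_{ch}": float(np.nanmean(
                interpolate_gaps(rec.channels[ch], max_run=interp_max_run).values))
            for ch in TREND_CHANNELS
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(TREND_MEAN_COLUMNS)]


def build_feature_set(
    level: int,
    metadata: pd.DataFrame,
    records: list[TrendRecord] | None = None,
    transient_features: pd.DataFrame | None = None,
    metric: str | None = None,
    window_hours: float | None = None,
    duration_hours: float = 72.0,
) -> FeatureMatrix:
    """Assemble one of the nested feature sets.

    ``metadata`` must carry ``patient_id``, ``psh_risk`` and the level-I
    columns. Level II additionally needs the trend ``records``; level III
    needs the long-format ``transient_features`` table plus exactly one
    ``metric`` and ``window_hours``. Column order is deterministic.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"unknown feature-set level {level!r}")
    missing_cols = [c for c in ("patient_id", "psh_risk", *LEVEL1_COLUMNS)
                    if c not in metadata.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks required columns: {missing_cols}")

    X = metadata.set_index("patient_id")[list(LEVEL1_COLUMNS)].astype(float)
    y = metadata.set_index("patient_id")["psh_risk"].astype(int)

    if level >= 2:
        if records is None:
            raise ValueError("level >= 2 requires the trend records")
        means = _trend_means(records)
        X = X.join(means, how="left")

    if level == 3:
        if transient_features is None:
            raise ValueError("level 3 requires the transient feature table")
        if metric not in METRICS:
            raise ValueError(f"level 3 requires one metric of {METRICS}, got {metric!r}")
        if window_hours is None:
            raise ValueError("level 3 requires a window length")
        sub = transient_features[
            (transient_features["metric"] == metric)
            & (transient_features["window_h"] == window_hours)
        ]
        nb = n_bins_for_window(duration_hours, window_hours)
        cols: dict[str, pd.Series] = {}
        for pair in SIGNAL_PAIRS:
            key = f"{pair[0]}-{pair[1]}"
            psub = sub[sub["pair"] == key].pivot(
                index="patient_id", columns="bin_index", values="value")
            for b in range(nb):
                name = transient_column_name(pair, metric, window_hours, b)
                cols[name] = (
                    psub[b] if b in psub.columns
                    else pd.Series(np.nan, index=X.index)
                )
        X = X.join(pd.DataFrame(cols, index=X.index), how="left")

    return FeatureMatrix(X=X, y=y, level=level, metric=metric,
                         window_hours=window_hours)


_FLAG_VARS = {
    "sex_male", "trauma_multiorgan",
    "ct_sdh", "ct_edh", "ct_tich", "ct_edema", "ct_dai", "ct_tsah",
}


def compare_groups(
    table: pd.DataFrame,
    by: str = "psh_risk",
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable group comparison in the style of a cohort table.

    Numeric variables: median (IQR) per group with a two-sided
    Mann-Whitney U test. Binary flags: count (%) per group with Fisher's
    exact test. Both groups must be non-empty.
    """
    groups = table[by].astype(int)
    if groups.nunique() < 2:
        raise ValueError("both outcome groups must be non-empty")
    if variables is None:
        variables = [c for c in table.columns
                     if c not in (by, "patient_id")]
    g1 = table[groups == 1]
    g0 = table[groups == 0]
    rows = []
    for var in variables:
        a, b = g1[var].dropna(), g0[var].dropna()
        if var in _FLAG_VARS or set(table[var].dropna().unique()) <= {0, 1}:
            n1, n0 = int(a.sum()), int(b.sum())
            ct = [[n1, len(a) - n1], [n0, len(b) - n0]]
            p = stats.fisher_exact(ct)[1]
            summary1 = f"{n1} ({100 * n1 / max(len(a), 1):.0f}%)"
            summary0 = f"{n0} ({100 * n0 / max(len(b), 1):.0f}%)"
            kind = "flag"
        else:
            # exact null distribution when there are no ties
            method = "exact" if pd.concat([a, b]).is_unique else "asymptotic"
            p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method=method).pvalue
            q1 = np.percentile(a, [50, 25, 75])
            q0 = np.percentile(b, [50, 25, 75])
            summary1 = f"{q1[0]:.1f} ({q1[1]:.1f}-{q1[2]:.1f})"
            summary0 = f"{q0[0]:.1f} ({q0[1]:.1f}-{q0[2]:.1f})"
            kind = "numeric"
        rows.append({
            "variable": var,
            "kind": kind,
            "group1": summary1,
            "group0": summary0,
            "p_value": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)
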