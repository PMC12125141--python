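"""Feature importance, additive attributions and the temporal profile.

Two complementary views of the cross-validated logistic model:

* coefficient importance — the absolute regression coefficients of each
  fold's fit (meaningful across features because fitting standardizes);
* additive attribution — the exact per-instance decomposition of the
  linear predictor relative to a background: for a linear model the
  Shapley attribution of feature j for instance i is
  ``coef_j * (x_ij - background_j)``, and attributions plus the base
  value reconstruct the linear predictor exactly.

Per-feature values are aggregated by summed absolute value across all
folds (and validation instances, for attributions) and min-max rescaled
to [0, 1]. The temporal significance profile aggregates the normalized
importance of each time bin's transient features across the six signal
pairs; bins strictly exceeding the mean of the per-bin values form the
"most influential" timespan.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CVReport, FoldFit

__all__ = [
    "ImportanceProfile",
    "TemporalProfile",
    "coefficient_importance",
    "additive_attribution",
    "aggregate_normalize",
    "importance_from_report",
    "attribution_importance_from_report",
    "pair_importance",
    "temporal_profile",
]

_TRANSIENT_RE = re.compile(
    r"^(?P<metric>[a-z]+)_(?P<ans>[a-z]+)_(?P<hemo>[a-z]+)_w(?P<w>[\d.]+)_b(?P<b>\d+)$"
)


@dataclass
class ImportanceProfile:
    """Min-max normalized per-feature importance for one method."""

    method: str                      # "coefficient" or "attribution"
    feature_names: list[str]
    raw: np.ndarray                  # aggregated absolute values
    normalized: np.ndarray           # in [0, 1]

    def as_series(self) -> pd.Series:
        return pd.Series(self.normalized, index=self.feature_names,
                         name=self.method)


@dataclass
class TemporalProfile:
    """Per-bin aggregated importance of the transient features."""

    method: str
    bin_index: np.ndarray
    values: np.ndarray               # per-bin aggregate (mean across pairs)
    threshold: float                 # mean of the per-bin values
    influential_bins: list[int]      # bins strictly above the threshold


def coefficient_importance(cv_report: CVReport) -> pd.DataFrame:
    """|coefficient| per feature per fold (folds x features)."""
    rows = [np.abs(f.coef) for f in cv_report.best_folds]
    return pd.DataFrame(rows, columns=cv_report.feature_names,
                        index=[f.fold for f in cv_report.best_folds])


def additive_attribution(
    coef: np.ndarray,
    intercept: float,
    X: np.ndarray,
    background: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact additive attributions of a linear model.

    Returns ``(phi, base)`` with ``phi[i, j] = coef[j] * (X[i, j] -
    background[j])`` and ``base = intercept + coef @ background``; then
    ``phi.sum(axis=1) + base`` equals the linear predictor exactly.
    """
    coef = np.asarray(coef, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.asarray(background, dtype=float)
    if X.shape[1] != coef.size or background.size != coef.size:
        raise ValueError("coef, X and background must agree on feature count")
    phi = coef[None, :] * (X - background[None, :])
    base = float(intercept + coef @ background)
    return phi, base


def fold_attributions(fold: FoldFit, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Attributions of one fold's model for its validation instances.

    Operates in the fold's standardized feature space; the background is
    the training-fold feature mean (the origin after z-scoring on
    training statistics).
    """
    Xt_val = fold.transform(X[fold.val_idx])
    background = fold.transform(X[fold.train_idx]).mean(axis=0)
    return additive_attribution(fold.coef, fold.intercept, Xt_val, background)


def aggregate_normalize(
    per_fold_values: list[np.ndarray],
    feature_names: list[str],
    method: str,
) -> ImportanceProfile:
    """Sum absolute values across folds/instances, then min-max to [0, 1].

    Each element of ``per_fold_values`` is either a vector (one value per
    feature) or a matrix (instances x features); matrices are reduced by
    the sum of absolute values over instances first. If every aggregated
    value is equal the normalization is degenerate and all-zero values
    are returned with a warning.
    """
    if not per_fold_values:
        raise ValueError("need at least one fold")
    total = np.zeros(len(feature_names))
    for v in per_fold_values:
        v = np.abs(np.asarray(v, dtype=float))
        if v.ndim == 2:
            v = v.sum(axis=0)
        if v.size != total.size:
            raise ValueError("fold values must match the feature count")
        total += v
    span = total.max() - total.min()
    if span == 0:
        warnings.warn("all aggregated importances equal; normalization degenerate")
        normalized = np.zeros_like(total)
    else:
        normalized = (total - total.min()) / span
    return ImportanceProfile(
        method=method, feature_names=list(feature_names),
        raw=total, normalized=normalized,
    )


def importance_from_report(cv_report: CVReport) -> ImportanceProfile:
    """Aggregated, normalized coefficient importance across CV folds."""
    return aggregate_normalize(
        [np.abs(f.coef) for f in cv_report.best_folds],
        cv_report.feature_names,
        method="coefficient",
    )


def attribution_importance_from_report(
    cv_report: CVReport, X: np.ndarray
) -> ImportanceProfile:
    """Aggregated, normalized attribution importance across CV folds.

    ``X`` is the raw (unstandardized) feature matrix the report was fit
    on; each fold contributes the absolute attributions of its
    validation instances.
    """
    per_fold = []
    for fold in cv_report.best_folds:
        phi, _ = fold_attributions(fold, np.asarray(X, dtype=float))
        per_fold.append(np.abs(phi))
    return aggregate_normalize(per_fold, cv_report.feature_names,
                               method="attribution")


def _transient_frame(profile: ImportanceProfile) -> pd.DataFrame:
    rows = []
    for name, norm in zip(profile.feature_names, profile.normalized):
        m = _TRANSIENT_RE.match(name)
        if m:
            rows.append({
                "feature": name,
                "pair": f"{m['ans']}-{m['hemo']}",
                "bin_index": int(m["b"]),
                "normalized": float(norm),
            })
    return pd.DataFrame(rows)


def pair_importance(profile: ImportanceProfile) -> pd.Series:
    """Normalized importance summed over bins, per signal pair (descending)."""
    frame = _transient_frame(profile)
    if frame.empty:
        raise ValueError("profile contains no transient features")
    return frame.groupby("pair")["normalized"].sum().sort_values(ascending=False)


def temporal_profile(profile: ImportanceProfile) -> TemporalProfile:
    """Per-bin aggregated importance and the influential timespan.

    Each bin's value is the mean of the normalized importances of that
    bin's transient features across the six pairs; the threshold is the
    mean of the per-bin values and exceeding it is strict, so a flat
    profile yields an empty influential span.
    """
    frame = _transient_frame(profile)
    if frame.empty:
        raise ValueError("profile contains no transient features")
    per_bin = frame.groupby("bin_index")["normalized"].mean().sort_index()
    threshold = float(per_bin.mean())
    influential = [int(b) for b, v in per_bin.items() if v > threshold]
    return TemporalProfile(
        method=profile.method,
        bin_index=per_bin.index.to_numpy(),
        values=per_bin.to_numpy(),
        threshold=threshold,
        influential_bins=influential,
    )
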