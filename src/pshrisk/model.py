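"""Cross-validated logistic-regression PSH-risk model.

The classifier is an L2-penalized logistic regression evaluated by
stratified five-fold cross-validation. The hyperparameter grid spans the
regularization strengths {2N, N, 1, 1/N, 1/(2N)} — interpreted as the
inverse penalty weight (sklearn's ``C``), so larger values mean weaker
penalty, with N the cohort size — crossed with balanced and unbalanced
class weighting. Performance is reported as mean +/- sd of ROC AUC and
accuracy across folds.

Imputation (fold-local training medians) and standardization are fitted
inside each training fold only; nothing from a validation fold leaks
into preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix

__all__ = [
    "ModelConfig",
    "FoldFit",
    "ConfigResult",
    "CVReport",
    "default_strength_grid",
    "stratified_folds",
    "fit_logistic",
    "cross_validate",
    "grid_search_cv",
]

WEIGHTINGS = ("balanced", "unbalanced")


def default_strength_grid(n_instances: int) -> tuple[float, ...]:
    """{2N, N, 1, 1/N, 1/(2N)} with N the number of instances."""
    n = float(n_instances)
    return (2 * n, n, 1.0, 1.0 / n, 1.0 / (2 * n))


@dataclass
class ModelConfig:
    strengths: tuple[float, ...] | None = None   # None: derive from N
    weightings: tuple[str, ...] = WEIGHTINGS
    k_folds: int = 5
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.strengths is not None and any(s <= 0 for s in self.strengths):
            raise ValueError("regularization strengths must be positive")
        unknown = set(self.weightings) - set(WEIGHTINGS)
        if unknown:
            raise ValueError(f"unknown weighting(s): {sorted(unknown)}")


@dataclass
class FoldFit:
    """One training fold's fitted model, in the standardized feature space."""

    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    coef: np.ndarray
    intercept: float
    imputer_fill: np.ndarray
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    zero_variance: list[str]
    auc: float
    acc: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the fold's (training-fitted) imputation and scaling."""
        X = np.asarray(X, dtype=float).copy()
        nan = np.isnan(X)
        X[nan] = np.broadcast_to(self.imputer_fill, X.shape)[nan]
        return (X - self.scale_mean) / self.scale_sd

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.coef + self.intercept


@dataclass
class ConfigResult:
    strength: float
    weighting: str
    fold_auc: list[float]
    fold_acc: list[float]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_auc, ddof=1))

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.fold_acc))

    @property
    def sd_acc(self) -> float:
        return float(np.std(self.fold_acc, ddof=1))


@dataclass
class CVReport:
    feature_names: list[str]
    fold_assignment: np.ndarray
    configs: list[ConfigResult]
    best_strength: float
    best_weighting: str
    best_folds: list[FoldFit]
    seed: int
    level: int | None = None
    metric: str | None = None
    window_hours: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def best(self) -> ConfigResult:
        for c in self.configs:
            if c.strength == self.best_strength and c.weighting == self.best_weighting:
                return c
        raise LookupError("best configuration missing from results")

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "fold_assignment": self.fold_assignment.tolist(),
            "seed": self.seed,
            "level": self.level,
            "metric": self.metric,
            "window_hours": self.window_hours,
            "configs": [
                {
                    "strength": c.strength,
                    "weighting": c.weighting,
                    "fold_auc": c.fold_auc,
                    "fold_acc": c.fold_acc,
                    "mean_auc": c.mean_auc,
                    "sd_auc": c.sd_auc,
                    "mean_acc": c.mean_acc,
                    "sd_acc": c.sd_acc,
                }
                for c in self.configs
            ],
            "best": {
                "strength": self.best_strength,
                "weighting": self.best_weighting,
                "mean_auc": self.best.mean_auc,
                "sd_auc": self.best.sd_auc,
                "mean_acc": self.best.mean_acc,
                "sd_acc": self.best.sd_acc,
                "folds": [
                    {
                        "fold": f.fold,
                        "coef": f.coef.tolist(),
                        "intercept": f.intercept,
                        "auc": f.auc,
                        "acc": f.acc,
                        "zero_variance": f.zero_variance,
                        "train_idx": f.train_idx.tolist(),
                        "val_idx": f.val_idx.tolist(),
                        "imputer_fill": f.imputer_fill.tolist(),
                        "scale_mean": f.scale_mean.tolist(),
                        "scale_sd": f.scale_sd.tolist(),
                    }
                    for f in self.best_folds
                ],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CVReport":
        configs = [
            ConfigResult(
                strength=c["strength"], weighting=c["weighting"],
                fold_auc=list(c["fold_auc"]), fold_acc=list(c["fold_acc"]),
            )
            for c in d["configs"]
        ]
        folds = [
            FoldFit(
                fold=f["fold"],
                train_idx=np.asarray(f["train_idx"], dtype=int),
                val_idx=np.asarray(f["val_idx"], dtype=int),
                coef=np.asarray(f["coef"], dtype=float),
                intercept=float(f["intercept"]),
                imputer_fill=np.asarray(f["imputer_fill"], dtype=float),
                scale_mean=np.asarray(f["scale_mean"], dtype=float),
                scale_sd=np.asarray(f["scale_sd"], dtype=float),
                zero_variance=list(f["zero_variance"]),
                auc=float(f["auc"]),
                acc=float(f["acc"]),
            )
            for f in d["best"]["folds"]
        ]
        return cls(
            feature_names=list(d["feature_names"]),
            fold_assignment=np.asarray(d["fold_assignment"], dtype=int),
            configs=configs,
            best_strength=d["best"]["strength"],
            best_weighting=d["best"]["weighting"],
            best_folds=folds,
            seed=d["seed"],
            level=d.get("level"),
            metric=d.get("metric"),
            window_hours=d.get("window_hours"),
        )


def stratified_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold id per instance; per-fold class counts differ by at most one."""
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y)
    if counts.size < 2 or (counts[counts > 0] < k).any():
        raise ValueError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        assignment[val_idx] = fold
    return assignment


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    strength: float,
    weighting: str = "balanced",
    standardize: bool = True,
) -> Pipeline:
    """Median-impute, optionally z-score, and fit the penalized logistic model.

    ``strength`` is the inverse L2 penalty weight (larger = weaker
    penalty). All preprocessing statistics come from the rows passed in,
    so calling this on a training fold alone guarantees no leakage.
    """
    if strength <= 0:
        raise ValueError("strength must be positive")
    steps = [("impute", SimpleImputer(strategy="median", keep_empty_features=True))]
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append((
        "logreg",
        LogisticRegression(
            C=strength,
            class_weight="balanced" if weighting == "balanced" else None,
            solver="lbfgs",
            tol=1e-8,
            max_iter=5000,
        ),
    ))
    pipe = Pipeline(steps)
    pipe.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int))
    return pipe


def _fold_fit(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    fold: int,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    strength: float,
    weighting: str,
    standardize: bool,
) -> FoldFit:
    pipe = fit_logistic(X[train_idx], y[train_idx], strength, weighting, standardize)
    proba = pipe.predict_proba(X[val_idx])[:, 1]
    auc = roc_auc_score(y[val_idx], proba)
    acc = accuracy_score(y[val_idx], (proba >= 0.5).astype(int))
    imputer: SimpleImputer = pipe.named_steps["impute"]
    fill = np.asarray(imputer.statistics_, dtype=float)
    fill = np.where(np.isnan(fill), 0.0, fill)
    if standardize:
        scaler: StandardScaler = pipe.named_steps["scale"]
        mean, sd = scaler.mean_.copy(), scaler.scale_.copy()
    else:
        k = len(feature_names)
        mean, sd = np.zeros(k), np.ones(k)
    coef = pipe.named_steps["logreg"].coef_[0].copy()
    intercept = float(pipe.named_steps["logreg"].intercept_[0])
    Xt = X[train_idx].copy()
    nan = np.isnan(Xt)
    Xt[nan] = np.broadcast_to(fill, Xt.shape)[nan]
    zero_var = [feature_names[j] for j in np.nonzero(np.ptp(Xt, axis=0) == 0)[0]]
    return FoldFit(
        fold=fold, train_idx=train_idx, val_idx=val_idx,
        coef=coef, intercept=intercept,
        imputer_fill=fill, scale_mean=mean, scale_sd=sd,
        zero_variance=zero_var, auc=float(auc), acc=float(acc),
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    fold_assignment: np.ndarray,
    strength: float,
    weighting: str,
    standardize: bool = True,
) -> list[FoldFit]:
    """Fit/evaluate one configuration over the given fold assignment."""
    fits = []
    for fold in np.unique(fold_assignment):
        val_idx = np.nonzero(fold_assignment == fold)[0]
        train_idx = np.nonzero(fold_assignment != fold)[0]
        fits.append(_fold_fit(
            X, y, feature_names, int(fold), train_idx, val_idx,
            strength, weighting, standardize,
        ))
    return fits


def grid_search_cv(features: FeatureMatrix, config: ModelConfig) -> CVReport:
    """Stratified k-fold CV over the full (strength x weighting) grid.

    The best configuration has the highest mean AUC; ties go to the
    smaller strength (stronger penalty), then to balanced weighting.
    """
    X = features.X.to_numpy(dtype=float)
    y = features.y.to_numpy()
    names = features.feature_names
    strengths = config.strengths or default_strength_grid(len(y))
    fold_assignment = stratified_folds(y, k=config.k_folds, seed=config.seed)

    results: list[ConfigResult] = []
    all_fits: dict[tuple[float, str], list[FoldFit]] = {}
    for strength in strengths:
        for weighting in config.weightings:
            fits = cross_validate(
                X, y, names, fold_assignment, strength, weighting,
                config.standardize,
            )
            all_fits[(strength, weighting)] = fits
            results.append(ConfigResult(
                strength=strength,
                weighting=weighting,
                fold_auc=[f.auc for f in fits],
                fold_acc=[f.acc for f in fits],
            ))

    def sort_key(c: ConfigResult):
        return (-c.mean_auc, c.strength, 0 if c.weighting == "balanced" else 1)

    best = min(results, key=sort_key)
    return CVReport(
        feature_names=names,
        fold_assignment=fold_assignment,
        configs=results,
        best_strength=best.strength,
        best_weighting=best.weighting,
        best_folds=all_fits[(best.strength, best.weighting)],
        seed=config.seed,
        level=features.level,
        metric=features.metric,
        window_hours=features.window_hours,
    )
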