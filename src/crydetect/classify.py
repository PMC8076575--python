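"""Classifier training, model selection and per-epoch prediction.

Three model families are compared for cry/non-cry epoch classification:
two discriminative (random forest, L2 logistic regression) and one
generative (Gaussian naive Bayes). For each family a stratified 5-fold
cross-validated grid search is run; because missing a cry is worse than a
false alarm, hyperparameters are chosen to maximize mean cross-validated
sensitivity, with mean MCC as the tie-break and grid order as the final
deterministic tie-break. The family with the highest mean cross-validated
MCC is then refit on all training rows as the final model.

Feature scaling: logistic regression and naive Bayes see z-scored
features (fit on training folds only); random forest sees raw features.
The decision threshold on the cry probability is fixed at 0.5, with the
boundary labeled cry (probability >= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .metrics import MetricSet, compute_metrics, confusion
from .sequences import EpochLabelSeries

FAMILIES = ("random_forest", "logistic_regression", "naive_bayes")
DEFAULT_THRESHOLD = 0.5


def default_grids() -> dict[str, list[dict]]:
    """Deterministic hyperparameter grids per family (documented defaults)."""
    rf = [
        {"n_estimators": n, "max_depth": d, "min_samples_leaf": leaf}
        for n in (100, 300, 500)
        for d in (None, 10, 20)
        for leaf in (1, 5)
    ]
    lr = [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)]
    nb = [{"var_smoothing": v} for v in (1e-9, 1e-6)]
    return {"random_forest": rf, "logistic_regression": lr, "naive_bayes": nb}


def make_estimator(family: str, params: dict, seed: int = 0):
    """Build the sklearn estimator (with scaling where the model needs it)."""
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "logistic_regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("model", LogisticRegression(max_iter=2000, **params)),
            ]
        )
    if family == "naive_bayes":
        return Pipeline(
            [("scale", StandardScaler()), ("model", GaussianNB(**params))]
        )
    raise ValueError(f"unknown model family: {family!r} (expected one of {FAMILIES})")


@dataclass
class LabeledDataset:
    """Feature matrix plus per-row binary labels (1 = cry)."""

    matrix: pd.DataFrame
    labels: np.ndarray
    feature_names: tuple[str, ...] = ()
    provenance: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not self.feature_names:
            self.feature_names = tuple(
                c for c in self.matrix.columns if c not in ("epoch_index", "start_time_s")
            )
        if len(self.matrix) != self.labels.size:
            raise ValueError(
                f"matrix has {len(self.matrix)} rows but {self.labels.size} labels"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    @property
    def X(self) -> np.ndarray:
        return self.matrix[list(self.feature_names)].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.labels


@dataclass
class CVResult:
    family: str
    params: dict
    fold_metrics: list[MetricSet]

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.fold_metrics]))

    def sd(self, metric: str) -> float:
        return float(np.std([getattr(m, metric) for m in self.fold_metrics], ddof=1))

    def summary(self) -> dict:
        metrics = ("accuracy", "mcc", "sensitivity", "specificity", "ppv", "npv")
        return {
            "family": self.family,
            "params": {k: v for k, v in self.params.items()},
            "mean": {m: self.mean(m) for m in metrics},
            "sd": {m: self.sd(m) for m in metrics},
            "folds": [m.as_dict() for m in self.fold_metrics],
        }


@dataclass
class TrainedModel:
    family: str
    params: dict
    estimator: object
    feature_names: tuple[str, ...]
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def _check_registry(self, matrix: pd.DataFrame) -> None:
        missing = [n for n in self.feature_names if n not in matrix.columns]
        if missing:
            raise ValueError(
                f"feature matrix is missing {len(missing)} model features, "
                f"e.g. {missing[:5]}"
            )

    def predict_proba(self, matrix: pd.DataFrame) -> np.ndarray:
        self._check_registry(matrix)
        if len(matrix) == 0:
            return np.empty(0, dtype=np.float64)
        X = matrix[list(self.feature_names)].to_numpy(dtype=np.float64)
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def _cv_metrics(family, params, X, y, k, seed) -> list[MetricSet]:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(X, y):
        est = make_estimator(family, params, seed=seed)
        est.fit(X[train_idx], y[train_idx])
        proba = est.predict_proba(X[test_idx])
        classes = list(est.classes_)
        p1 = proba[:, classes.index(1)]
        pred = (p1 >= DEFAULT_THRESHOLD).astype(np.int64)
        folds.append(compute_metrics(confusion(y[test_idx], pred)))
    return folds


def pick_best(candidates: list[tuple[dict, float, float]]) -> dict:
    """Sensitivity-first hyperparameter choice.

    ``candidates`` is a list of (params, mean_sensitivity, mean_mcc) in
    grid order; the winner maximizes sensitivity, ties broken by MCC,
    remaining ties by grid order (first wins).
    """
    if not candidates:
        raise ValueError("no hyperparameter candidates")
    best = candidates[0]
    for cand in candidates[1:]:
        if cand[1] > best[1] or (cand[1] == best[1] and cand[2] > best[2]):
            best = cand
    return best[0]


def grid_search_cv(
    data: LabeledDataset,
    family: str,
    k: int = 5,
    seed: int = 0,
    grid: list[dict] | None = None,
) -> CVResult:
    """Stratified k-fold grid search for one family.

    Returns the CVResult of the winning hyperparameters (their fold
    metrics, not a refit).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family: {family!r}")
    X, y = data.X, data.y
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training data must contain both classes")
    if k > min(n_pos, n_neg):
        raise ValueError(
            f"k={k} folds exceed the minority class count ({min(n_pos, n_neg)})"
        )
    grid = grid if grid is not None else default_grids()[family]
    evaluated = []
    for params in grid:
        folds = _cv_metrics(family, params, X, y, k, seed)
        evaluated.append((params, folds))
    candidates = [
        (params, float(np.mean([m.sensitivity for m in folds])),
         float(np.mean([m.mcc for m in folds])))
        for params, folds in evaluated
    ]
    best_params = pick_best(candidates)
    best_folds = next(f for p, f in evaluated if p is best_params)
    return CVResult(family=family, params=best_params, fold_metrics=best_folds)


def select_final_model(
    results: list[CVResult], data: LabeledDataset, seed: int = 0
) -> TrainedModel:
    """Pick the family with the highest mean CV MCC and refit on all rows.

    Ties fall back to the documented family order
    (random_forest, logistic_regression, naive_bayes).
    """
    if not results:
        raise ValueError("select_final_model requires at least one CVResult")
    order = {f: i for i, f in enumerate(FAMILIES)}
    best = max(results, key=lambda r: (r.mean("mcc"), -order.get(r.family, len(order))))
    est = make_estimator(best.family, best.params, seed=seed)
    est.fit(data.X, data.y)
    return TrainedModel(
        family=best.family,
        params=best.params,
        estimator=est,
        feature_names=tuple(data.feature_names),
        seed=seed,
    )


def predict_epochs(
    model: TrainedModel, matrix: pd.DataFrame, subject: str | None = None
) -> tuple[EpochLabelSeries, np.ndarray]:
    """Per-epoch cry probability and thresholded label series."""
    proba = model.predict_proba(matrix)
    labels = (proba >= model.threshold).astype(np.int64)
    return EpochLabelSeries(labels=labels, subject=subject), proba
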