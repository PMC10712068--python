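"""Bioactivity-classification harness for comparing split strategies.

Random-forest classifiers on radius-2 Morgan fingerprint features, with:

* nested cross-validation for hyperparameter choice (outer 5-fold /
  inner 2-fold grid search; the grid point chosen most often across the
  outer folds wins, and a run is flagged unstable when all five folds pick
  different points);
* a decision threshold tuned to maximize Cohen's kappa on training-data
  probabilities (out-of-bag when available), scanning 0.05..0.95 in steps of
  0.05;
* the metric battery: ROC AUC (raw probabilities), balanced accuracy, F1,
  precision, recall and Cohen's kappa.

When one strategy is evaluated over several seeds, hyperparameters are chosen
on the first seed's training set only and reused for the rest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    balanced_accuracy_score,
    cohen_kappa_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict

from .data import AssayDataset, Split
from .fingerprints import fingerprint_array

__all__ = [
    "ModelSpec",
    "EvalRow",
    "featurize",
    "select_hyperparameters",
    "optimize_threshold",
    "evaluate_model",
    "run_benchmark",
]

THRESHOLD_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)

METRICS = ("auc", "balanced_accuracy", "f1", "precision", "recall", "kappa")


@dataclass(frozen=True)
class ModelSpec:
    """Random-forest hyperparameter grid and CV layout."""

    max_depth: tuple[int, ...] = (20, 40)
    min_samples_leaf: tuple[int, ...] = (2, 4)
    n_estimators: tuple[int, ...] = (100, 300)
    outer_folds: int = 5
    inner_folds: int = 2
    fp_radius: int = 2
    fp_bits: int = 2048

    @property
    def grid(self) -> list[dict]:
        return [
            {"max_depth": d, "min_samples_leaf": l, "n_estimators": n}
            for d, l, n in itertools.product(
                self.max_depth, self.min_samples_leaf, self.n_estimators
            )
        ]


@dataclass
class EvalRow:
    """Metrics of one (strategy, seed) evaluation."""

    strategy: str
    seed: int | None
    metrics: dict[str, float]
    hyperparameters: dict
    threshold: float
    unstable: bool


def featurize(smiles_list, *, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Binary Morgan fingerprint feature matrix (rows = molecules)."""
    return fingerprint_array(smiles_list, radius=radius, n_bits=n_bits)


def select_hyperparameters(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec = ModelSpec(), seed: int = 0
) -> tuple[dict, bool]:
    """Nested-CV hyperparameter choice.

    Each of the 5 outer folds runs an inner 2-fold grid search on its training
    part; the modal winning grid point is returned (ties broken by grid
    order). The instability flag is set only when all five outer folds choose
    distinct grid points.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    outer = StratifiedKFold(n_splits=spec.outer_folds, shuffle=True, random_state=seed)
    param_grid = {
        "max_depth": list(spec.max_depth),
        "min_samples_leaf": list(spec.min_samples_leaf),
        "n_estimators": list(spec.n_estimators),
    }
    picks = []
    for fold_train, _ in outer.split(X, y):
        inner = StratifiedKFold(spec.inner_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(
            RandomForestClassifier(random_state=seed, n_jobs=1),
            param_grid,
            cv=inner,
            n_jobs=1,
        )
        search.fit(X[fold_train], y[fold_train])
        picks.append(tuple(sorted(search.best_params_.items())))
    unstable = len(set(picks)) == spec.outer_folds
    grid_keys = [tuple(sorted(p.items())) for p in spec.grid]
    counts = {k: picks.count(k) for k in set(picks)}
    best = max(grid_keys, key=lambda k: (counts.get(k, 0), -grid_keys.index(k)))
    return dict(best), unstable


def optimize_threshold(
    model: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    *,
    grid: np.ndarray = THRESHOLD_GRID,
    seed: int = 0,
) -> float:
    """Kappa-maximizing decision threshold on training probabilities.

    Uses the model's out-of-bag probabilities when available, otherwise
    5-fold cross-predicted probabilities. Ties are broken toward 0.5 (then
    toward the lower threshold).
    """
    if getattr(model, "oob_decision_function_", None) is not None:
        proba = model.oob_decision_function_[:, 1]
        proba = np.nan_to_num(proba, nan=0.5)  # compounds never out of bag
    else:
        proba = cross_val_predict(
            model,
            X,
            y,
            cv=StratifiedKFold(5, shuffle=True, random_state=seed),
            method="predict_proba",
            n_jobs=1,
        )[:, 1]
    if np.ptp(proba) == 0:
        import warnings

        warnings.warn("degenerate probabilities; using threshold 0.5", stacklevel=2)
        return 0.5
    kappas = np.array(
        [cohen_kappa_score(y, proba >= t) for t in grid]
    )
    best_kappa = kappas.max()
    tied = grid[kappas == best_kappa]
    return float(tied[np.argmin(np.abs(tied - 0.5))])


def evaluate_model(
    model: RandomForestClassifier,
    threshold: float,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> dict[str, float]:
    """Metric battery on a held-out test set.

    AUC is computed from raw probabilities (it is threshold-invariant); the
    remaining metrics use predictions at the tuned threshold. AUC is reported
    as NaN for a single-class test set.
    """
    proba = model.predict_proba(X_test)[:, 1]
    pred = proba >= threshold
    auc = (
        float(roc_auc_score(y_test, proba)) if len(np.unique(y_test)) > 1 else np.nan
    )
    return {
        "auc": auc,
        "balanced_accuracy": float(balanced_accuracy_score(y_test, pred)),
        "f1": float(f1_score(y_test, pred, zero_division=0)),
        "precision": float(precision_score(y_test, pred, zero_division=0)),
        "recall": float(recall_score(y_test, pred, zero_division=0)),
        "kappa": float(cohen_kappa_score(y_test, pred)),
    }


def _fit_and_score(
    X: np.ndarray, y: np.ndarray, split_idx, params: dict, seed: int
) -> tuple[dict[str, float], float]:
    train_idx, test_idx = split_idx
    model = RandomForestClassifier(
        **params, random_state=seed, oob_score=True, n_jobs=1
    )
    model.fit(X[train_idx], y[train_idx])
    threshold = optimize_threshold(model, X[train_idx], y[train_idx], seed=seed)
    return evaluate_model(model, threshold, X[test_idx], y[test_idx]), threshold


def run_benchmark(
    dataset: AssayDataset,
    splits_by_strategy: dict[str, list[Split]],
    spec: ModelSpec = ModelSpec(),
    *,
    select_on_first: bool = True,
) -> tuple[pd.DataFrame, list[EvalRow]]:
    """Evaluate one model pipeline per (strategy, split).

    For each strategy, hyperparameters are selected by nested CV on the first
    split's training set and reused for the remaining splits. Returns a tidy
    per-row frame plus structured rows; per-strategy medians/sds can be taken
    directly from the frame.
    """
    X = featurize(dataset.smiles, radius=spec.fp_radius, n_bits=spec.fp_bits)
    y = dataset.labels()
    rows: list[EvalRow] = []
    for strategy, splits in splits_by_strategy.items():
        params: dict | None = None
        unstable = False
        for split in splits:
            split.validate(dataset)
            train_idx = split.train_index(dataset)
            test_idx = split.test_index(dataset)
            seed = split.seed if split.seed is not None else 0
            if params is None or not select_on_first:
                params, unstable = select_hyperparameters(
                    X[train_idx], y[train_idx], spec, seed=seed
                )
            metrics, threshold = _fit_and_score(
                X, y, (train_idx, test_idx), params, seed
            )
            rows.append(EvalRow(strategy, split.seed, metrics, params, threshold, unstable))
    frame = pd.DataFrame(
        [
            {"strategy": r.strategy, "seed": r.seed, **r.metrics,
             "threshold": r.threshold, "unstable": r.unstable}
            for r in rows
        ]
    )
    return frame, rows
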