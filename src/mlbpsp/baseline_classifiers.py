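"""Predicting longitudinal phenotype from baseline scores only.

Two tasks: a four-class random forest evaluated with stratified 10-fold
cross-validation, and a binary healthy-vs-other logistic regression.  Both
pool out-of-fold predictions and report accuracy, confusion, and (for the
binary task) the two misallocation rates: the fraction of predicted-healthy
participants who truly belong to a less healthy phenotype and vice versa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold


@dataclass
class ClassifierReport:
    """Cross-validated classification summary."""

    task: str  # "four-class" | "binary"
    accuracy: float
    misclassification: float
    confusion: pd.DataFrame  # rows = true, columns = predicted
    fold_assignments: pd.Series
    seed: int
    n_folds: int
    misallocation: dict | None = None  # binary task only


def _folds(labels: np.ndarray, n_folds: int, seed: int) -> tuple[int, StratifiedKFold]:
    _, counts = np.unique(labels, return_counts=True)
    smallest = int(counts.min())
    if smallest < n_folds:
        warnings.warn(
            f"smallest class has {smallest} members; reducing folds from "
            f"{n_folds} to {smallest}",
            stacklevel=3,
        )
        n_folds = max(smallest, 2)
    return n_folds, StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)


def _confusion(y_true: pd.Series, y_pred: pd.Series) -> pd.DataFrame:
    return pd.crosstab(y_true, y_pred, rownames=["true"], colnames=["predicted"], dropna=False)


def rf_crossval_phenotypes(
    baseline_scores: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    n_folds: int = 10,
    n_trees: int = 500,
) -> ClassifierReport:
    """Four-class random forest with stratified k-fold CV.

    ``baseline_scores`` is a complete numeric frame indexed like ``labels``
    (default predictors: depression total, global deficit score, functioning
    total, daily-living total).  Out-of-fold predictions are pooled.
    """
    X = baseline_scores.loc[labels.index].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("baseline scores contain missing values")
    y = labels.to_numpy()
    n_folds, splitter = _folds(y, n_folds, seed)

    pred = np.empty(len(y), dtype=labels.dtype)
    fold_of = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(splitter.split(X, y)):
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed
        )
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
        fold_of[test] = fold

    y_true = pd.Series(y, index=labels.index, name="true")
    y_pred = pd.Series(pred, index=labels.index, name="predicted")
    acc = float((y_true == y_pred).mean())
    return ClassifierReport(
        task="four-class",
        accuracy=acc,
        misclassification=1.0 - acc,
        confusion=_confusion(y_true, y_pred),
        fold_assignments=pd.Series(fold_of, index=labels.index, name="fold"),
        seed=seed,
        n_folds=n_folds,
    )


def binary_healthy_classifier(
    baseline_scores: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    n_folds: int = 10,
    healthy_label=1,
    threshold: float = 0.5,
) -> ClassifierReport:
    """Healthy-vs-other logistic regression with stratified k-fold CV.

    Labels are collapsed to healthy (== ``healthy_label``) vs other; a
    participant is predicted healthy when the out-of-fold probability is at
    least ``threshold`` (a threshold of 1.0 or more predicts nobody healthy).
    Misallocation rates are reported for each predicted group; an empty
    predicted group yields ``None`` for its rate.
    """
    X = baseline_scores.loc[labels.index].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("baseline scores contain missing values")
    y = (labels == healthy_label).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels collapse to a single class")
    n_folds, splitter = _folds(y, n_folds, seed)

    proba = np.empty(len(y))
    fold_of = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(splitter.split(X, y)):
        clf = LogisticRegression(C=np.inf, max_iter=2000)
        clf.fit(X[train], y[train])
        healthy_col = int(np.where(clf.classes_ == 1)[0][0])
        proba[test] = clf.predict_proba(X[test])[:, healthy_col]
        fold_of[test] = fold

    pred = (proba >= threshold).astype(int) if threshold < 1.0 else np.zeros(len(y), dtype=int)
    y_true = pd.Series(np.where(y == 1, "healthy", "other"), index=labels.index, name="true")
    y_pred = pd.Series(np.where(pred == 1, "healthy", "other"), index=labels.index, name="predicted")
    acc = float((y == pred).mean())

    def _misalloc(predicted_value: str, wrong_true: str):
        mask = y_pred == predicted_value
        if mask.sum() == 0:
            return None
        return float((y_true[mask] == wrong_true).mean())

    misallocation = {
        "predicted_healthy_truly_other": _misalloc("healthy", "other"),
        "predicted_other_truly_healthy": _misalloc("other", "healthy"),
    }
    return ClassifierReport(
        task="binary",
        accuracy=acc,
        misclassification=1.0 - acc,
        confusion=_confusion(y_true, y_pred),
        fold_assignments=pd.Series(fold_of, index=labels.index, name="fold"),
        seed=seed,
        n_folds=n_folds,
        misallocation=misallocation,
    )
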