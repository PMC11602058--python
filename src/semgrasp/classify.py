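"""Classifier training and stratified 10-fold evaluation with per-class metrics.

Three classifier kinds mirror the recognition stage of the pipeline:

* ``lda_quadratic`` — a discriminant classifier with a quadratic decision
  boundary (quadratic discriminant analysis); plain ``lda`` is also
  available.
* ``svm_poly2`` — a support-vector machine with the degree-2 polynomial
  kernel ``(x . y / n_features + 1)^2`` (one-vs-one multiclass, C = 1).
* ``bagging_tree`` — bagged decision trees aggregated by majority vote.

Features are standardised (zero mean, unit variance) with statistics fit
on the training folds only, since the feature space mixes units (mV, Hz,
nats).  Evaluation uses stratified k-fold cross-validation; per-class
accuracy/precision/recall/F1 are computed one-vs-rest from the pooled
confusion matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIER_KINDS",
    "EvalReport",
    "train_classifier",
    "crossval_evaluate",
    "report_tables",
]

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS: tuple[str, ...] = ("lda_quadratic", "lda", "svm_poly2", "bagging_tree")


@dataclass
class EvalReport:
    """Cross-validation outcome: pooled confusion matrix and derived metrics."""

    classes: list[str]
    confusion_matrix: np.ndarray  # (C, C), rows = true, columns = predicted
    per_class: pd.DataFrame  # index classes; accuracy/precision/recall/f1
    fold_accuracies: np.ndarray
    mean_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_accuracy = float(np.mean(self.fold_accuracies))


def _base_estimator(kind: str, *, seed: int | None = None,
                    n_trees: int = 100, svm_c: float = 1.0):
    if kind == "lda_quadratic":
        return QuadraticDiscriminantAnalysis()
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "svm_poly2":
        # gamma="auto" = 1/n_features, so the kernel is (x.y/d + 1)^2.
        return SVC(kernel="poly", degree=2, gamma="auto", coef0=1.0, C=svm_c)
    if kind == "bagging_tree":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=n_trees,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


def train_classifier(features: np.ndarray, labels: np.ndarray, kind: str, *,
                     seed: int | None = None, standardize: bool = True,
                     n_trees: int = 100, svm_c: float = 1.0):
    """Fit one classifier; returns an object exposing ``predict``.

    A singular within-class covariance in the discriminant classifiers is
    handled by refitting with a small regularisation term (logged), not
    by raising.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training needs at least 2 classes")
    est = _base_estimator(kind, seed=seed, n_trees=n_trees, svm_c=svm_c)
    steps = [("scale", StandardScaler())] if standardize else []
    model = Pipeline(steps + [("clf", est)])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model.fit(X, y)
        except np.linalg.LinAlgError:
            caught.append(None)  # force the regularised path
    if kind == "lda_quadratic" and any(
        c is None or "collinear" in str(c.message).lower() for c in caught
    ):
        logger.warning("singular within-class covariance; refitting with regularisation")
        est = QuadraticDiscriminantAnalysis(reg_param=1e-3)
        model = Pipeline(steps + [("clf", est)])
        model.fit(X, y)
    return model


def _per_class_metrics(cm: np.ndarray, classes: list[str]) -> pd.DataFrame:
    total = cm.sum()
    rows = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = total - tp - fp - fn
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        rows[c] = {
            "accuracy": (tp + tn) / total,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def crossval_evaluate(features: np.ndarray, labels: np.ndarray, kind: str, *,
                      folds: int = 10, seed: int = 0, standardize: bool = True,
                      groups: np.ndarray | None = None, n_trees: int = 100,
                      svm_c: float = 1.0) -> EvalReport:
    """Stratified k-fold cross-validation of one classifier kind.

    Fold assignment is deterministic under ``seed``.  Passing ``groups``
    (e.g. source-trial ids) switches to group-aware stratification so
    windows of one trial never straddle the train/test split.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    class_counts = pd.Series(y).value_counts()
    if groups is None and class_counts.min() < folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} samples, fewer than {folds} folds"
        )
    if groups is None:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    else:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y, groups=groups)

    cidx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    fold_acc = []
    for train, test in split_iter:
        model = train_classifier(
            X[train], y[train], kind,
            seed=seed, standardize=standardize, n_trees=n_trees, svm_c=svm_c,
        )
        pred = model.predict(X[test])
        fold_acc.append(float(np.mean(pred == y[test])))
        for t, p in zip(y[test], pred):
            cm[cidx[t], cidx[p]] += 1

    return EvalReport(
        classes=classes,
        confusion_matrix=cm,
        per_class=_per_class_metrics(cm, classes),
        fold_accuracies=np.asarray(fold_acc),
    )


def report_tables(report: EvalReport, *, as_csv: bool = False) -> str:
    """Format the per-class metric table (percentages, F1 as a ratio)."""
    df = report.per_class.copy()
    out = pd.DataFrame(index=df.index)
    for col in ("accuracy", "precision", "recall"):
        out[col.capitalize()] = (df[col] * 100).map("{:.2f}%".format)
    out["F1"] = df["f1"].map("{:.2f}".format)
    out.index.name = "Grasps"
    if as_csv:
        return out.to_csv()
    body = out.to_string()
    return f"{body}\nMean accuracy over folds: {report.mean_accuracy * 100:.2f}%"
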