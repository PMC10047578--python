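"""Stratified cross-validation and the seven-metric evaluation suite.

The abnormal class is the positive class throughout: sensitivity measures
the ability to flag disease-positive cervigrams.  Metrics reported per
classifier are accuracy, sensitivity, specificity, precision, recall
(identical to sensitivity by construction), mean absolute error of the
predicted class probabilities against the one-hot truth, and F1.

Cross-validation defaults to stratified 10-fold.  When the HOG block is in
play the PCA is, by default, refitted on each training split so no test
information leaks into the projection; ``paper_mode=True`` instead fits it
once on the full dataset, matching the single-pass protocol typical of
published feature-table workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConsistencyError, ParameterError, StratificationError
from .fusion import FeatureTables
from .hog import fit_pca
from .models import CLASSIFIER_NAMES, train_classifier

__all__ = [
    "POSITIVE_LABEL",
    "METRIC_COLUMNS",
    "FEATURE_SETS",
    "ConfusionCounts",
    "MetricsReport",
    "CvResult",
    "stratified_folds",
    "compute_metrics",
    "cross_validate",
    "run_experiment",
    "results_frame",
]

POSITIVE_LABEL = "abnormal"

#: Results-grid column order.
METRIC_COLUMNS = (
    "Accuracy",
    "Sensitivity",
    "Specificity",
    "Precision",
    "Recall",
    "MAE",
    "F1Measure",
)

FEATURE_SETS = ("glrlm", "glcm", "hog", "hybrid")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with abnormal as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass
class MetricsReport:
    """The seven summary statistics; ``degenerate`` flags zero-denominator ones."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    mae: float
    f1: float
    degenerate: tuple[str, ...] = ()

    def as_row(self) -> dict[str, float]:
        return {
            "Accuracy": self.accuracy,
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "Precision": self.precision,
            "Recall": self.recall,
            "MAE": self.mae,
            "F1Measure": self.f1,
        }


@dataclass
class CvResult:
    """Per-fold and pooled metrics for one (feature set, classifier) pair."""

    classifier: str
    feature_set: str
    fold_metrics: list[MetricsReport]
    pooled: MetricsReport
    pooled_counts: ConfusionCounts
    seed: int = 0


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
    probs: Optional[np.ndarray] = None,
    truth: Optional[np.ndarray] = None,
) -> MetricsReport:
    """Evaluate the seven metrics from confusion counts and class probabilities.

    ``probs`` is the per-instance probability of the positive (abnormal)
    class and ``truth`` the 0/1 truth vector; the MAE is then the mean over
    instances and both classes of |predicted probability - one-hot truth|.
    A metric with a zero denominator is reported as 0 and flagged.
    """
    flags: list[str] = []
    acc = _ratio(counts.tp + counts.tn, counts.total, "accuracy", flags)
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity", flags)
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity", flags)
    prec = _ratio(counts.tp, counts.tp + counts.fp, "precision", flags)
    recall = sens  # identical formula by definition
    f1 = _ratio(2.0 * prec * recall, prec + recall, "f1", flags)
    if probs is not None:
        probs = np.asarray(probs, dtype=np.float64)
        truth_arr = np.asarray(truth, dtype=np.float64)
        if probs.shape != truth_arr.shape:
            raise ConsistencyError("probs and truth must have the same length")
        # |p_pos - y_pos| == |p_neg - y_neg| for binary, so the per-class
        # average equals the positive-class absolute error
        mae = float(np.mean(np.abs(probs - truth_arr)))
    else:
        flags.append("mae")
        mae = 0.0
    return MetricsReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        recall=recall,
        mae=mae,
        f1=f1,
        degenerate=tuple(flags),
    )


def stratified_folds(labels, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Disjoint stratified test-index sets covering the data.

    Class proportions per fold are within one instance of the global
    proportions.  Raises :class:`StratificationError` when any class has
    fewer than ``k`` instances.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        lacking = classes[np.argmin(counts)]
        raise StratificationError(
            f"class {lacking!r} has {counts.min()} instances, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def _counts_from_predictions(y_true01, y_pred01) -> ConfusionCounts:
    y_true01 = np.asarray(y_true01)
    y_pred01 = np.asarray(y_pred01)
    return ConfusionCounts(
        tp=int(((y_true01 == 1) & (y_pred01 == 1)).sum()),
        tn=int(((y_true01 == 0) & (y_pred01 == 0)).sum()),
        fp=int(((y_true01 == 0) & (y_pred01 == 1)).sum()),
        fn=int(((y_true01 == 1) & (y_pred01 == 0)).sum()),
    )


def _design_matrix(
    tables: FeatureTables,
    feature_set: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    k: int,
    paper_mode: bool,
    global_pca,
) -> tuple[np.ndarray, np.ndarray]:
    parts_train, parts_test = [], []
    if feature_set in ("glrlm", "hybrid"):
        parts_train.append(tables.glrlm[train_idx])
        parts_test.append(tables.glrlm[test_idx])
    if feature_set in ("glcm", "hybrid"):
        parts_train.append(tables.glcm[train_idx])
        parts_test.append(tables.glcm[test_idx])
    if feature_set in ("hog", "hybrid"):
        model = global_pca if paper_mode else fit_pca(tables.hog_raw[train_idx], k=k)
        parts_train.append(model.transform(tables.hog_raw[train_idx]))
        parts_test.append(model.transform(tables.hog_raw[test_idx]))
    return np.hstack(parts_train), np.hstack(parts_test)


def cross_validate(
    tables: FeatureTables,
    classifier: str,
    feature_set: str = "hybrid",
    k_folds: int = 10,
    seed: int = 0,
    pca_components: int = 20,
    paper_mode: bool = False,
) -> CvResult:
    """Stratified k-fold CV of one classifier on one feature set."""
    if feature_set not in FEATURE_SETS:
        raise ParameterError(f"unknown feature set {feature_set!r}")
    y01 = (tables.labels == POSITIVE_LABEL).astype(np.int64)
    folds = stratified_folds(tables.labels, k=k_folds, seed=seed)
    all_idx = np.arange(len(tables))
    global_pca = tables.hog_pca(pca_components) if (
        paper_mode and feature_set in ("hog", "hybrid")
    ) else None

    fold_metrics: list[MetricsReport] = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    pooled_probs = np.empty(len(tables))
    pooled_pred = np.empty(len(tables), dtype=np.int64)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        Xtr, Xte = _design_matrix(
            tables, feature_set, train_idx, test_idx, pca_components,
            paper_mode, global_pca,
        )
        model = train_classifier(classifier, Xtr, y01[train_idx], seed=seed)
        pred = np.asarray(model.predict(Xte)).astype(np.int64)
        proba = model.predict_proba(Xte)
        pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
        p_pos = np.asarray(proba)[:, pos_col]
        counts = _counts_from_predictions(y01[test_idx], pred)
        fold_metrics.append(compute_metrics(counts, p_pos, y01[test_idx]))
        pooled_counts = pooled_counts + counts
        pooled_probs[test_idx] = p_pos
        pooled_pred[test_idx] = pred
    pooled = compute_metrics(pooled_counts, pooled_probs, y01)
    return CvResult(
        classifier=classifier,
        feature_set=feature_set,
        fold_metrics=fold_metrics,
        pooled=pooled,
        pooled_counts=pooled_counts,
        seed=seed,
    )


def run_experiment(
    tables: FeatureTables,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    feature_sets: Sequence[str] = FEATURE_SETS,
    k_folds: int = 10,
    seed: int = 0,
    pca_components: int = 20,
    paper_mode: bool = False,
) -> dict[tuple[str, str], CvResult]:
    """The full benchmark grid: every feature set crossed with every classifier."""
    results: dict[tuple[str, str], CvResult] = {}
    for fs in feature_sets:
        for clf in classifiers:
            results[(fs, clf)] = cross_validate(
                tables, clf, fs, k_folds=k_folds, seed=seed,
                pca_components=pca_components, paper_mode=paper_mode,
            )
    return results


def results_frame(
    results: dict[tuple[str, str], CvResult]
) -> dict[str, pd.DataFrame]:
    """One metric grid per feature set: classifier rows x the seven metric columns."""
    grids: dict[str, pd.DataFrame] = {}
    feature_sets = sorted({fs for fs, _ in results})
    for fs in feature_sets:
        rows = {
            clf: results[(fs, clf)].pooled.as_row()
            for fs2, clf in results
            if fs2 == fs
        }
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_COLUMNS)
        frame.index.name = "Classifier"
        grids[fs] = frame
    return grids
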