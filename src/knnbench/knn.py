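"""Metric-pluggable k-nearest-neighbour classification and its evaluation.

The classifier is the textbook lazy learner: a query is assigned the
majority label among its k closest training rows under an arbitrary
distance from :mod:`knnbench.metrics`.  No tree acceleration and no
distance weighting — distances are computed exhaustively, which is what
makes the classifier exactly pluggable for any dissimilarity, including
ones that are not true metrics.

Performance is summarised by one-vs-rest confusion counts per class and
the four derived measures (precision, recall, F1, accuracy), macro- or
micro-averaged over classes.  :func:`evaluate_metric_on_dataset` runs the
full seeded protocol: repeated stratified splits, predictions for every
k in a grid, scores averaged over repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import multilabel_confusion_matrix
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .exceptions import (
    DegenerateInputError,
    DimensionError,
    DomainError,
    ParameterError,
    ProtocolError,
)
from .metrics import MetricSpec

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledDataset",
    "EvalProtocol",
    "ConfusionCounts",
    "PerformanceScores",
    "PERFORMANCE_MEASURES",
    "knn_predict",
    "confusion_counts",
    "performance_scores",
    "evaluate_metric_on_dataset",
]

PERFORMANCE_MEASURES = ("precision", "recall", "f1", "accuracy")


@dataclass
class LabeledDataset:
    """Numeric observations with class labels.

    ``features`` is an (n_samples, n_features) float matrix with no
    missing values; ``labels`` holds one class identifier per row and at
    least two distinct classes must be present.
    """

    features: np.ndarray
    labels: np.ndarray
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[1] == 0:
            raise DimensionError("features must be a non-empty 2-D matrix")
        if len(self.labels) != len(self.features):
            raise DimensionError(
                f"{len(self.labels)} labels for {len(self.features)} feature rows"
            )
        if not np.all(np.isfinite(self.features)):
            raise DomainError("features contain NaN or infinite values")
        if len(np.unique(self.labels)) < 2:
            raise ParameterError("a labeled dataset needs at least 2 distinct classes")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass(frozen=True)
class EvalProtocol:
    """Seeded evaluation protocol for one dataset.

    ``k_values`` is the neighbourhood grid; ``split_fraction`` the train
    share of each stratified shuffle split; ``repetitions`` the number of
    splits averaged over (for ``scheme="kfold"`` it is the number of
    folds).  ``averaging`` selects macro or micro aggregation of the
    per-class measures.
    """

    k_values: tuple[int, ...] = tuple(range(1, 21))
    split_fraction: float = 0.7
    repetitions: int = 10
    seed: int = 0
    averaging: str = "macro"
    scheme: str = "shuffle"

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.k_values)
        if not ks or any(k < 1 for k in ks):
            raise ParameterError("k_values must be positive integers")
        object.__setattr__(self, "k_values", ks)
        if not 0.0 < self.split_fraction < 1.0:
            raise ParameterError("split_fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise ParameterError("repetitions must be >= 1")
        if self.averaging not in ("macro", "micro"):
            raise ParameterError(f"unknown averaging {self.averaging!r}")
        if self.scheme not in ("shuffle", "kfold"):
            raise ParameterError(f"unknown scheme {self.scheme!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest tally for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceScores:
    precision: float
    recall: float
    f1: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }


def _vote(codes: np.ndarray, dists: np.ndarray, n_classes: int, tie_policy: str) -> int:
    """Majority vote over neighbour class codes; deterministic tie handling.

    ``nearest_sum`` resolves a tied vote in favour of the tied class whose
    neighbours have the smallest summed distance; any remaining tie (and
    the ``label_order`` policy) picks the smallest class code.
    """
    counts = np.bincount(codes, minlength=n_classes)
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if len(tied) == 1:
        return int(tied[0])
    if tie_policy == "nearest_sum":
        tied_sums = np.array([np.sum(dists[codes == c]) for c in tied])
        winners = tied[tied_sums == tied_sums.min()]
        return int(winners.min())
    return int(tied.min())


def knn_predict(
    train: LabeledDataset,
    query,
    k: int,
    metric: MetricSpec,
    tie_policy: str = "nearest_sum",
):
    """Classify a single query vector by majority vote of its k nearest rows.

    Distance ties at the k-th rank are broken by training-row index
    (stable sort); vote ties per ``tie_policy``.
    """
    if tie_policy not in ("nearest_sum", "label_order"):
        raise ParameterError(f"unknown tie_policy {tie_policy!r}")
    if not 1 <= k <= train.n_samples:
        raise ParameterError(
            f"k={k} out of range for training set of {train.n_samples} rows"
        )
    query = np.asarray(query, dtype=float)
    if query.ndim != 1 or query.size != train.n_features:
        raise DimensionError(
            f"query has {query.size} features, training data has {train.n_features}"
        )
    try:
        dists = np.asarray(metric(train.features, query), dtype=float)
    except Exception as exc:  # annotate with context, re-raise
        raise type(exc)(f"metric {metric.label()!r} failed on training rows: {exc}") from exc
    order = np.argsort(dists, kind="stable")[:k]
    classes, codes_all = np.unique(train.labels, return_inverse=True)
    code = _vote(codes_all[order], dists[order], len(classes), tie_policy)
    return classes[code]


def confusion_counts(y_true: Sequence, y_pred: Sequence) -> dict:
    """One-vs-rest TP/TN/FP/FN tallies for every observed class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise DimensionError("y_true and y_pred must be equal-length non-empty sequences")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    mats = multilabel_confusion_matrix(y_true, y_pred, labels=classes)
    return {
        cls: ConfusionCounts(tp=int(m[1, 1]), tn=int(m[0, 0]), fp=int(m[0, 1]), fn=int(m[1, 0]))
        for cls, m in zip(classes, mats)
    }


def performance_scores(counts: Mapping, averaging: str = "macro") -> PerformanceScores:
    """Precision, recall, F1 and accuracy from per-class confusion counts.

    Per-class precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
    harmonic mean; a class never predicted (TP+FP = 0) contributes
    precision 0 with a logged warning.  ``macro`` averages the per-class
    values with equal class weight; ``micro`` pools the counts first.
    Accuracy is the overall fraction of correctly classified samples.
    """
    if not counts:
        raise DegenerateInputError("performance_scores needs counts for at least one class")
    if averaging not in ("macro", "micro"):
        raise ParameterError(f"unknown averaging {averaging!r}")
    items = list(counts.items())
    n = items[0][1].total
    if len(items) == 1:
        # single positive-class view: (TP+TN)/total
        c = items[0][1]
        accuracy = (c.tp + c.tn) / n
    else:
        # complete one-vs-rest family: sum of per-class TP counts every
        # correctly classified sample exactly once
        accuracy = sum(c.tp for _, c in items) / n

    if averaging == "micro":
        tp = sum(c.tp for _, c in items)
        fp = sum(c.fp for _, c in items)
        fn = sum(c.fn for _, c in items)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        return PerformanceScores(precision, recall, f1, accuracy)

    precisions, recalls, f1s = [], [], []
    for cls, c in items:
        if c.tp + c.fp == 0:
            logger.warning("class %r never predicted; precision set to 0", cls)
            p = 0.0
        else:
            p = c.tp / (c.tp + c.fp)
        r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    return PerformanceScores(
        float(np.mean(precisions)), float(np.mean(recalls)), float(np.mean(f1s)), accuracy
    )


def _splits(labels: np.ndarray, protocol: EvalProtocol):
    classes, class_counts = np.unique(labels, return_counts=True)
    thin = classes[class_counts < 2]
    if len(thin):
        raise ProtocolError(
            f"class {thin[0]!r} has fewer than 2 members; stratified splitting impossible"
        )
    if protocol.scheme == "kfold":
        splitter = StratifiedKFold(
            n_splits=protocol.repetitions, shuffle=True, random_state=protocol.seed
        )
    else:
        splitter = StratifiedShuffleSplit(
            n_splits=protocol.repetitions,
            train_size=protocol.split_fraction,
            random_state=protocol.seed,
        )
    for train_idx, test_idx in splitter.split(np.zeros(len(labels)), labels):
        for part, part_name in ((train_idx, "training"), (test_idx, "test")):
            present = np.unique(labels[part])
            if len(present) < len(classes):
                missing = sorted(set(classes) - set(present))
                raise ProtocolError(
                    f"class {missing[0]!r} absent from {part_name} partition; "
                    "increase the dataset or adjust split_fraction"
                )
        yield train_idx, test_idx


def evaluate_metric_on_dataset(
    data: LabeledDataset,
    metric: MetricSpec,
    protocol: EvalProtocol,
    tie_policy: str = "nearest_sum",
) -> pd.DataFrame:
    """Score one metric on one dataset over the full (measure, k) grid.

    For each repetition a seeded stratified train/test split is drawn; for
    every k in the protocol's grid all test rows are classified and the
    four performance measures computed.  Scores are averaged over
    repetitions.  Returns a long DataFrame with columns
    ``performance, k, score`` — one slice of the benchmark score tensor.

    The distance matrix between test and training rows is computed once
    per split and reused across the whole k grid, so the cost is one
    pairwise pass per (repetition, metric).
    """
    max_k = max(protocol.k_values)
    acc: dict[tuple[str, int], list[float]] = {
        (p, k): [] for p in PERFORMANCE_MEASURES for k in protocol.k_values
    }
    for train_idx, test_idx in _splits(data.labels, protocol):
        if max_k > len(train_idx):
            raise ProtocolError(
                f"max k={max_k} exceeds training partition size {len(train_idx)}"
            )
        X_train = data.features[train_idx]
        X_test = data.features[test_idx]
        y_train = data.labels[train_idx]
        y_test = data.labels[test_idx]
        classes, train_codes = np.unique(y_train, return_inverse=True)

        dmat = metric.pairwise(X_test, X_train)
        order = np.argsort(dmat, axis=1, kind="stable")[:, :max_k]
        sorted_codes = train_codes[order]
        sorted_dists = np.take_along_axis(dmat, order, axis=1)

        for k in protocol.k_values:
            pred_codes = [
                _vote(sorted_codes[i, :k], sorted_dists[i, :k], len(classes), tie_policy)
                for i in range(len(test_idx))
            ]
            y_pred = classes[np.asarray(pred_codes)]
            scores = performance_scores(
                confusion_counts(y_test, y_pred), averaging=protocol.averaging
            )
            for p, value in scores.as_dict().items():
                acc[(p, k)].append(value)

    rows = [
        {"performance": p, "k": k, "score": float(np.mean(vals))}
        for (p, k), vals in acc.items()
    ]
    return pd.DataFrame(rows, columns=["performance", "k", "score"])
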