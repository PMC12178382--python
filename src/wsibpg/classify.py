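"""Slide classification: distance-weighted k-NN with grid-searched k.

Slide vectors are compared by cosine distance

    D_C(v_q, v_p) = 1 - (v_q . v_p) / (||v_q|| ||v_p||),

and a test slide is assigned the class with the largest summed inverse
distance 1/(D_C + eps) among its k nearest training slides (eps = 1e-12,
so an exact duplicate dominates the vote). k is chosen by stratified inner
cross-validation on the training set over the odd grid 1, 3, ..., 19
(heuristically, 1 up to the nearest odd number to the square root of the
reference-set size), maximizing weighted-F1 with ties going to the
smaller k.

Scoring is class-support-weighted: per class i, precision_i =
TP_i/(TP_i+FP_i), recall_i = TP_i/(TP_i+FN_i), F1_i their harmonic mean
(0/0 -> 0), and the aggregate is sum_i w_i F1_i / sum_i w_i with w_i the
true class support — appropriate for an imbalanced cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .pooling import SlideVector

__all__ = [
    "KNNConfig",
    "ClassificationReport",
    "cosine_distance",
    "knn_fit_predict",
    "weighted_scores",
]

_EPS = 1e-12


@dataclass(frozen=True)
class KNNConfig:
    k_grid: tuple[int, ...] = tuple(range(1, 20, 2))
    inner_cv_folds: int = 5
    # weighting is inverse-distance and the metric cosine by construction

    def __post_init__(self) -> None:
        if len(self.k_grid) == 0:
            raise ValueError("k_grid must be nonempty")
        if any(k < 1 for k in self.k_grid):
            raise ValueError("all k must be >= 1")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")


@dataclass
class ClassificationReport:
    classes: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    chosen_k: int | None = None


def cosine_distance(v_q: np.ndarray, v_p: np.ndarray) -> float:
    """1 minus cosine similarity; 0 for parallel, 1 for orthogonal vectors."""
    a = np.asarray(v_q, dtype=np.float64).ravel()
    b = np.asarray(v_p, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - (a @ b) / (na * nb))


def _as_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return np.asarray(vectors, dtype=np.float64)
    if len(vectors) and isinstance(vectors[0], SlideVector):
        return np.stack([v.vector for v in vectors]).astype(np.float64)
    return np.asarray(vectors, dtype=np.float64)


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), _EPS)
    return np.clip(1.0 - An @ Bn.T, 0.0, 2.0)


def _weighted_vote(
    dist: np.ndarray, train_labels: np.ndarray, k: int, classes: list
) -> list:
    """Predict each row of ``dist`` by inverse-distance vote over its k
    nearest columns."""
    k = min(k, dist.shape[1])
    preds = []
    for row in dist:
        nn = np.argpartition(row, k - 1)[:k]
        weights = 1.0 / (row[nn] + _EPS)
        votes = {c: 0.0 for c in classes}
        for j, w in zip(nn, weights):
            votes[train_labels[j]] += w
        preds.append(max(votes, key=lambda c: (votes[c], )))
    return preds


def knn_fit_predict(
    train_vectors,
    train_labels: Sequence[str],
    test_vectors,
    config: KNNConfig = KNNConfig(),
) -> tuple[list[str], int]:
    """Grid-search k on the training half, then predict the test slides.

    Returns ``(predictions, chosen_k)``. The inner stratified CV scores
    each k by weighted-F1; ties resolve to the smaller k. A degenerate
    single-entry grid skips the search.
    """
    X_train = _as_matrix(train_vectors)
    X_test = _as_matrix(test_vectors)
    y_train = np.asarray(list(train_labels), dtype=object)
    if X_train.shape[0] != y_train.shape[0]:
        raise ValueError("training vectors and labels must align")
    if X_train.shape[0] < max(config.k_grid):
        raise ValueError("training set smaller than the largest k in the grid")
    classes = sorted(set(y_train.tolist()))

    if len(config.k_grid) == 1:
        chosen_k = config.k_grid[0]
    else:
        _, counts = np.unique(y_train, return_counts=True)
        folds = min(config.inner_cv_folds, int(counts.min()))
        if folds < 2:
            raise ValueError(
                "every class needs at least 2 members for the inner CV"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=False)
        scores = {k: [] for k in config.k_grid}
        for fit_idx, val_idx in skf.split(X_train, y_train):
            dist = _cosine_matrix(X_train[val_idx], X_train[fit_idx])
            for k in config.k_grid:
                preds = _weighted_vote(dist, y_train[fit_idx], k, classes)
                scores[k].append(
                    weighted_scores(y_train[val_idx].tolist(), preds).weighted_f1
                )
        chosen_k = min(
            config.k_grid, key=lambda k: (-float(np.mean(scores[k])), k)
        )

    dist = _cosine_matrix(X_test, X_train)
    preds = _weighted_vote(dist, y_train, chosen_k, classes)
    return preds, chosen_k


def weighted_scores(
    y_true: Sequence[str], y_pred: Sequence[str]
) -> ClassificationReport:
    """Per-class precision/recall/F1 and their support-weighted means."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must align")
    classes = sorted(set(y_true) | set(y_pred))
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    weights = supp.astype(float)
    total = weights.sum()
    return ClassificationReport(
        classes=classes,
        precision=dict(zip(classes, map(float, prec))),
        recall=dict(zip(classes, map(float, rec))),
        f1=dict(zip(classes, map(float, f1))),
        support=dict(zip(classes, map(int, supp))),
        weighted_precision=float((weights * prec).sum() / total),
        weighted_recall=float((weights * rec).sum() / total),
        weighted_f1=float((weights * f1).sum() / total),
    )
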