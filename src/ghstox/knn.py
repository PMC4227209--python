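"""k-nearest-neighbor classification with Euclidean distances.

A query is assigned the majority class of its k nearest training rows.
Descriptors are autoscaled with statistics computed from the training rows
only, and the same scaling is applied to held-out queries, so all
descriptors contribute comparably to the Euclidean distance.

Tie-breaking is deterministic: among vote-tied classes the class of the
nearest neighbor belonging to a tied class wins; distance ties between
training rows are resolved in favor of the lower row index.

``k`` is selected by cross-validation: the grid value with the highest
cross-validated non-error rate wins, smallest k on ties.  The default fold
scheme is venetian blinds (row i -> fold i mod F).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .metrics import confusion, class_metrics


class KNNError(ValueError):
    pass


def _scaling(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Training-set autoscaling statistics; a zero-SD column gets scale 1 so
    it contributes nothing to distances instead of dividing by zero."""
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    scales = np.where(scales == 0, 1.0, scales)
    return means, scales


@dataclass
class KNNModel:
    """Fitted k-NN state: scaled training matrix, labels, k and the scaling."""

    train_values: np.ndarray  # autoscaled (n, p)
    train_labels: np.ndarray  # (n,) int class ids
    k: int
    means: np.ndarray
    scales: np.ndarray
    column_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.train_values = np.asarray(self.train_values, dtype=float)
        self.train_labels = np.asarray(self.train_labels, dtype=int)
        n = self.train_values.shape[0]
        if self.train_labels.shape[0] != n:
            raise KNNError("labels/matrix length mismatch")
        if not 1 <= self.k <= n - 1:
            raise KNNError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {self.k}")

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "ghstox-knn/1",
            "k": int(self.k),
            "train_values": self.train_values.tolist(),
            "train_labels": self.train_labels.tolist(),
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "column_names": self.column_names,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "KNNModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "ghstox-knn/1":
            raise KNNError(f"{path}: not a recognized k-NN model bundle")
        return cls(
            train_values=np.array(payload["train_values"], dtype=float),
            train_labels=np.array(payload["train_labels"], dtype=int),
            k=int(payload["k"]),
            means=np.array(payload["means"], dtype=float),
            scales=np.array(payload["scales"], dtype=float),
            column_names=payload.get("column_names"),
        )


def fit_knn(
    raw_train: np.ndarray,
    labels: Sequence[int],
    k: int,
    column_names: Optional[Sequence[str]] = None,
) -> KNNModel:
    """Autoscale the training matrix and wrap it in a :class:`KNNModel`."""
    X = np.asarray(raw_train, dtype=float)
    means, scales = _scaling(X)
    return KNNModel(
        train_values=(X - means) / scales,
        train_labels=np.asarray(labels, dtype=int),
        k=k,
        means=means,
        scales=scales,
        column_names=list(column_names) if column_names is not None else None,
    )


def _vote(neighbor_labels: np.ndarray) -> int:
    """Majority vote; tied classes resolved by the nearest tied neighbor.

    ``neighbor_labels`` must already be ordered by increasing distance
    (index tie-break applied).
    """
    classes, counts = np.unique(neighbor_labels, return_counts=True)
    best = counts.max()
    tied = set(classes[counts == best].tolist())
    if len(tied) == 1:
        return int(next(iter(tied)))
    for lab in neighbor_labels:
        if int(lab) in tied:
            return int(lab)
    raise AssertionError("unreachable: some neighbor belongs to a tied class")


def _neighbor_order(d2: np.ndarray) -> np.ndarray:
    """Order training indices by (distance, index): stable argsort on d2."""
    return np.argsort(d2, axis=1, kind="stable")


def knn_predict(model: KNNModel, raw_queries: np.ndarray) -> np.ndarray:
    """Classify query rows (raw scale; the model's scaling is applied)."""
    Q = np.asarray(raw_queries, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != model.train_values.shape[1]:
        raise KNNError(
            f"query has {Q.shape[-1] if Q.ndim == 2 else '?'} columns, "
            f"model expects {model.train_values.shape[1]}"
        )
    Z = (Q - model.means) / model.scales
    # Squared Euclidean distances; monotone in distance, so ordering is equal.
    d2 = (
        np.sum(Z**2, axis=1)[:, None]
        + np.sum(model.train_values**2, axis=1)[None, :]
        - 2 * Z @ model.train_values.T
    )
    order = _neighbor_order(d2)
    out = np.empty(Q.shape[0], dtype=int)
    for i in range(Q.shape[0]):
        out[i] = _vote(model.train_labels[order[i, : model.k]])
    return out


def knn_fit_predictions(model: KNNModel) -> np.ndarray:
    """Predict each training row from its k nearest OTHER training rows.

    The row itself is excluded, so with k=1 the fitting non-error rate can
    be below 1 — including self would make fitting trivially perfect.
    """
    X = model.train_values
    n = X.shape[0]
    if n < model.k + 1:
        raise KNNError("need at least k+1 training rows for fitting predictions")
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, np.inf)
    order = _neighbor_order(d2)
    out = np.empty(n, dtype=int)
    for i in range(n):
        out[i] = _vote(model.train_labels[order[i, : model.k]])
    return out


def make_cv_folds(
    n: int, n_folds: int = 5, scheme: str = "venetian", seed: Optional[int] = None
) -> np.ndarray:
    """Fold assignment for n rows.

    ``venetian`` (default): row i -> fold i mod n_folds, the deterministic
    blind pattern.  ``random``: a seeded uniform shuffle of the venetian
    assignment.
    """
    if n_folds < 2:
        raise KNNError(f"n_folds must be >= 2, got {n_folds}")
    if n < n_folds:
        raise KNNError(f"need n >= n_folds, got n={n}, n_folds={n_folds}")
    folds = np.arange(n) % n_folds
    if scheme == "venetian":
        return folds
    if scheme == "random":
        rng = np.random.default_rng(seed)
        return rng.permutation(folds)
    raise KNNError(f"unknown fold scheme {scheme!r}")


def cv_predictions(
    raw_values: np.ndarray,
    labels: Sequence[int],
    k: int,
    folds: np.ndarray,
) -> np.ndarray:
    """Pooled cross-validated predictions.

    For each fold, a model is fit on the remaining rows (scaling recomputed
    from those rows only) and the held-out rows are predicted.
    """
    X = np.asarray(raw_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    folds = np.asarray(folds)
    preds = np.empty(X.shape[0], dtype=int)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        model = fit_knn(X[train], y[train], k=min(k, int(train.sum()) - 1))
        preds[test] = knn_predict(model, X[test])
    return preds


def select_k(
    raw_values: np.ndarray,
    labels: Sequence[int],
    k_grid: Sequence[int] = tuple(range(1, 11)),
    folds: Optional[np.ndarray] = None,
    n_folds: int = 5,
    class_order: Optional[Sequence[int]] = None,
) -> tuple[int, dict[int, float]]:
    """Choose k by cross-validated non-error rate; smallest k on ties."""
    if not len(k_grid):
        raise KNNError("k_grid must be non-empty")
    y = np.asarray(labels, dtype=int)
    if folds is None:
        folds = make_cv_folds(len(y), n_folds=n_folds)
    if class_order is None:
        class_order = sorted(set(y.tolist()))
    smallest_fold_train = min(
        int(np.sum(folds != f)) for f in np.unique(folds)
    )
    ner_by_k: dict[int, float] = {}
    for k in k_grid:
        if k >= smallest_fold_train:
            raise KNNError(f"k={k} exceeds the smallest training-fold size")
        preds = cv_predictions(raw_values, y, k=k, folds=folds)
        cm = confusion(y, preds, class_order=class_order)
        ner_by_k[int(k)] = class_metrics(cm).ner
    best_k = max(sorted(ner_by_k), key=lambda k: (ner_by_k[k], -k))
    return best_k, ner_by_k
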