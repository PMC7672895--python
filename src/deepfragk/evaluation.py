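"""Classification metrics and the ten-fold cross-validation protocol.

A note on naming: in this method's literature "specificity" denotes the
fraction of predicted members of a class that truly belong to it — i.e.
per-class *precision* — and "sensitivity" denotes recall.  Both are
macro-averaged (unweighted class means).  The conventional true-negative
specificity is reported alongside for completeness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = ["ConfusionMatrix", "CVReport", "confusion", "metrics", "ten_fold_cv"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row = true class, column = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class CVReport:
    per_fold_metrics: list
    aggregate: dict
    per_class: dict
    pooled: dict = field(default_factory=dict)


def confusion(true_labels, predicted_labels, n: int) -> ConfusionMatrix:
    """Tally counts[i][j] = #(true=i, predicted=j) over n classes."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    if len(t) == 0:
        return ConfusionMatrix(np.zeros((n, n), dtype=np.int64))
    if t.min() < 0 or t.max() >= n or p.min() < 0 or p.max() >= n:
        raise ValueError(f"labels outside [0, {n})")
    return ConfusionMatrix(_sk_confusion(t, p, labels=np.arange(n)))


def metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy plus macro precision-style specificity and recall sensitivity.

    Classes never predicted (or never true) contribute 0 to the respective
    macro mean, with a logged note.
    """
    counts = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    pred_tot = counts.sum(axis=0).astype(float)
    true_tot = counts.sum(axis=1).astype(float)
    precision = np.divide(tp, pred_tot, out=np.zeros_like(tp),
                          where=pred_tot > 0)
    recall = np.divide(tp, true_tot, out=np.zeros_like(tp), where=true_tot > 0)
    never_pred = np.where(pred_tot == 0)[0]
    never_true = np.where(true_tot == 0)[0]
    if len(never_pred):
        logger.info("classes never predicted (precision counted as 0): %s",
                    never_pred.tolist())
    if len(never_true):
        logger.info("classes with no true items (recall counted as 0): %s",
                    never_true.tolist())
    tn = cm.total - pred_tot - true_tot + tp
    fp = pred_tot - tp
    tn_specificity = np.divide(tn, tn + fp, out=np.zeros_like(tp),
                               where=(tn + fp) > 0)
    return {
        "accuracy": float(tp.sum() / cm.total),
        "macro_specificity": float(precision.mean()),
        "macro_sensitivity": float(recall.mean()),
        "macro_tn_specificity": float(tn_specificity.mean()),
        "per_class": {
            "precision": precision,
            "recall": recall,
            "tn_specificity": tn_specificity,
            "support": true_tot.astype(int),
        },
        "flagged_classes": {"never_predicted": never_pred.tolist(),
                            "never_true": never_true.tolist()},
    }


def ten_fold_cv(X, y, train_fn, eval_fn=None, seed: int = 0,
                n_splits: int = 10) -> CVReport:
    """Stratified k-fold protocol: train on 9/10, evaluate on the held-out 1/10.

    ``train_fn(X_train, y_train)`` returns a model; ``eval_fn(model, X_test)``
    returns predicted labels (defaults to ``model.predict``).  The aggregate
    reports the unweighted mean ± sd over partitions; the pooled block
    recomputes the metrics over all out-of-fold predictions at once.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(y) < n_splits:
        raise ValueError(f"need at least {n_splits} items for {n_splits}-fold CV")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_splits:
        logger.warning("fewer than %d items in some class: stratification "
                       "degrades", n_splits)
    n_classes = int(y.max()) + 1
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    per_fold = []
    seen = np.zeros(len(y), dtype=int)
    pooled_true, pooled_pred = [], []
    for train_idx, test_idx in skf.split(X, y):
        seen[test_idx] += 1
        model = train_fn(X[train_idx], y[train_idx])
        predict = eval_fn if eval_fn is not None else (
            lambda m, Xt: m.predict(Xt))
        preds = np.asarray(predict(model, X[test_idx]))
        per_fold.append(metrics(confusion(y[test_idx], preds, n_classes)))
        pooled_true.append(y[test_idx])
        pooled_pred.append(preds)
    if not np.all(seen == 1):
        raise AssertionError("CV partitions do not cover the dataset exactly once")
    keys = ("accuracy", "macro_specificity", "macro_sensitivity")
    aggregate = {}
    for key in keys:
        vals = np.array([m[key] for m in per_fold])
        aggregate[key] = {"mean": float(vals.mean()), "sd": float(vals.std())}
    pooled_cm = confusion(np.concatenate(pooled_true),
                          np.concatenate(pooled_pred), n_classes)
    pooled = metrics(pooled_cm)
    per_class = pooled["per_class"]
    return CVReport(per_fold_metrics=per_fold, aggregate=aggregate,
                    per_class=per_class,
                    pooled={k: pooled[k] for k in keys})
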