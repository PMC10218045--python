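"""Evaluation metrics: feature-selection sensitivity/specificity and
confusion-derived classification metrics (accuracy, recall, precision, F1,
balanced accuracy).

Balanced accuracy is (sensitivity + specificity)/2 for binary outcomes and
the mean per-group recall for multiclass — the two coincide as macro recall.
Multiclass precision/recall/F1 are macro-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm


@dataclass
class SelectionOutcome:
    """Confusion counts of selected vs truly relevant features."""

    tp: np.ndarray  # per block
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> np.ndarray:
        return self.tn / (self.tn + self.fp)

    @property
    def pooled_sensitivity(self) -> float:
        return float(self.tp.sum() / (self.tp.sum() + self.fn.sum()))

    @property
    def pooled_specificity(self) -> float:
        return float(self.tn.sum() / (self.tn.sum() + self.fp.sum()))

    @property
    def mean_sensitivity(self) -> float:
        """Average of block-level sensitivities (alternative to pooling)."""
        return float(self.sensitivity.mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.specificity.mean())


def selection_metrics(selected, truth, m_per_block) -> SelectionOutcome:
    """Feature-selection confusion counts per block and pooled.

    Parameters
    ----------
    selected, truth : lists (one entry per block) of feature index arrays.
    m_per_block : total feature count per block.
    """
    if not (len(selected) == len(truth) == len(m_per_block)):
        raise ValueError("selected, truth and m_per_block must align per block")
    tp, fp, tn, fn = [], [], [], []
    for sel, tru, m in zip(selected, truth, m_per_block):
        sel = set(int(i) for i in np.asarray(sel, dtype=int).ravel())
        tru = set(int(i) for i in np.asarray(tru, dtype=int).ravel())
        if len(tru) == 0:
            raise ValueError("empty truth set: sensitivity is undefined")
        if sel and (min(sel) < 0 or max(sel) >= m):
            raise ValueError(f"selected index out of range for block of size {m}")
        if min(tru) < 0 or max(tru) >= m:
            raise ValueError(f"truth index out of range for block of size {m}")
        tp.append(len(sel & tru))
        fp.append(len(sel - tru))
        fn.append(len(tru - sel))
        tn.append(m - len(sel | tru))
    return SelectionOutcome(
        tp=np.array(tp), fp=np.array(fp), tn=np.array(tn), fn=np.array(fn)
    )


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean per-group recall ((sensitivity + specificity)/2 when binary)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    for c in np.unique(y_true):
        if not np.any(y_true == c):  # pragma: no cover - defensive
            raise ValueError(f"empty group {c!r} in test set")
    return float(_skm.balanced_accuracy_score(y_true, y_pred))


def balanced_accuracy_from_confusion(confusion) -> float:
    """Balanced accuracy from a confusion matrix (rows = true groups)."""
    confusion = np.asarray(confusion, dtype=float)
    row_sums = confusion.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every true group needs at least one test sample")
    return float(np.mean(np.diag(confusion) / row_sums))


@dataclass
class ClassificationReport:
    """Confusion-derived metrics for one classifier on one test set."""

    labels: np.ndarray
    confusion: np.ndarray
    accuracy: float
    recall_per_group: np.ndarray
    recall: float          # macro recall
    precision: float       # macro precision
    f1: float              # macro F1
    balanced_accuracy: float

    def to_dict(self) -> dict:
        return {
            "labels": [str(l) for l in self.labels],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "recall_per_group": self.recall_per_group.tolist(),
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "balanced_accuracy": self.balanced_accuracy,
        }


def classification_report(y_true, y_pred, labels=None) -> ClassificationReport:
    """Standard confusion-derived metrics (macro-averaged for multiclass)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = np.unique(y_true)
    labels = np.asarray(labels)
    unseen = np.setdiff1d(np.unique(y_pred), labels)
    if unseen.size:
        raise ValueError(f"predicted label(s) outside the known label set: {list(unseen)}")
    conf = _skm.confusion_matrix(y_true, y_pred, labels=labels)
    with np.errstate(invalid="ignore"):
        recalls = np.diag(conf) / conf.sum(axis=1)
    return ClassificationReport(
        labels=labels,
        confusion=conf,
        accuracy=float(_skm.accuracy_score(y_true, y_pred)),
        recall_per_group=recalls,
        recall=float(_skm.recall_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        precision=float(_skm.precision_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        f1=float(_skm.f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        balanced_accuracy=balanced_accuracy_from_confusion(conf),
    )
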