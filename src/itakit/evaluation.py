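"""Single-split performance surface: ROC-AUC and balanced error rate.

The study design evaluates every model on one stratified 80/20 train/test
split of the sample.  At ~1.5–2% outcome prevalence overall accuracy is
uninformative (the always-negative classifier scores 98%+), so performance is
summarised by AUC — the probability a random positive case outscores a random
negative one — and the balanced error rate (BER), the arithmetic mean of the
per-class misclassification rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split as _sk_split


class Confusion(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class EvalReport:
    auc: float
    ber: float
    confusion: Confusion
    threshold: float
    n_train: int | None = None
    n_test: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = dict(self.confusion._asdict())
        return d


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels


def auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal; ties get half credit).

    Equals the Mann-Whitney pairwise concordance P(score+ > score-) with ties
    counted 1/2.  Undefined when only one class is present.
    """
    labels = _check_labels(labels)
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def ber(confusion: Confusion) -> float:
    """Balanced error rate: ½·(FN/(TP+FN) + FP/(TN+FP))."""
    tp, fp, tn, fn = confusion.tp, confusion.fp, confusion.tn, confusion.fn
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("BER undefined: a class has no test members")
    return 0.5 * (fn / (tp + fn) + fp / (tn + fp))


def confusion_at(scores, labels, threshold: float) -> Confusion:
    labels = _check_labels(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    return Confusion(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def choose_threshold(scores, labels, mode: str = "balanced") -> float:
    """Decision threshold for the confusion matrix underlying BER.

    ``balanced`` (default) picks the probability cut maximizing balanced
    accuracy (equivalently Youden's J = TPR − FPR) on the data given — in the
    pipeline, always the *training* data.  ``fixed`` returns 0.5, which at
    very low prevalence classifies everything negative and pins BER at 0.5.
    """
    if mode == "fixed":
        return 0.5
    if mode != "balanced":
        raise ValueError("mode must be 'balanced' or 'fixed'")
    labels = _check_labels(labels)
    fpr, tpr, thresholds = roc_curve(labels, np.asarray(scores, dtype=float))
    j = tpr - fpr
    best = int(np.argmax(j))
    thr = float(thresholds[best])
    if not np.isfinite(thr):  # roc_curve's leading sentinel threshold
        thr = float(np.max(scores)) + 1.0
    return thr


def evaluate(scores, labels, threshold: float = 0.5,
             n_train: int | None = None) -> EvalReport:
    """AUC plus BER at ``threshold`` on one test set of scored cases."""
    labels = _check_labels(labels)
    conf = confusion_at(scores, labels, threshold)
    return EvalReport(
        auc=auc(scores, labels),
        ber=ber(conf),
        confusion=conf,
        threshold=float(threshold),
        n_train=n_train,
        n_test=int(len(labels)),
    )


def split_indices(y, train_fraction: float = 0.8, seed: int = 0,
                  stratified: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test row indices.

    Stratified mode preserves outcome prevalence on each side to within one
    record per class; at rare-outcome prevalence the non-stratified variant
    can strand all positives on one side, which triggers a warning.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    y = _check_labels(y)
    idx = np.arange(len(y))
    tr, te = _sk_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        shuffle=True,
        stratify=y if stratified else None,
    )
    if not stratified:
        for side, name in ((tr, "train"), (te, "test")):
            if y[side].min() == y[side].max():
                warnings.warn(
                    f"{name} split contains a single class; use stratified=True "
                    "at low prevalence",
                    UserWarning,
                )
    return np.sort(tr), np.sort(te)


def train_test_split(matrix, train_fraction: float = 0.8, seed: int = 0,
                     stratified: bool = True):
    """Split a DesignMatrix into (train, test) DesignMatrices."""
    tr, te = split_indices(matrix.y, train_fraction, seed, stratified)
    return matrix.take_rows(tr), matrix.take_rows(te)
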