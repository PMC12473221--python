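"""Classification metrics: ROC curves, AUC, mean AUC, and the DeLong test.

AUC follows the Mann-Whitney convention (ties between a positive and a
negative score credited 0.5).  The DeLong test compares two correlated AUCs
measured on the same samples using the structural-components covariance
estimator, returning a two-sided p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

__all__ = ["RocCurve", "roc_curve", "auc", "mean_auc", "delong_test"]


@dataclass
class RocCurve:
    """A swept ROC curve with the confusion counts behind every point."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    auc: float

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if labels.min() == labels.max():
        raise ValueError("need at least one positive and one negative sample")
    return labels


def roc_curve(scores, labels) -> RocCurve:
    """Sweep thresholds over the scores; FPR = FP/(FP+TN), TPR = TP/(TP+FN)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    tp = np.round(tpr * n_pos).astype(int)
    fp = np.round(fpr * n_neg).astype(int)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp,
                    auc=auc(scores, labels))


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties count 0.5)."""
    labels = _check_binary(labels)
    return float(_skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def mean_auc(per_label_auc) -> float:
    """Unweighted mean of per-label AUCs, skipping undefined (NaN) entries."""
    values = np.asarray(per_label_auc, dtype=float)
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        raise ValueError("no label has a defined AUC")
    if defined.size < values.size:
        warnings.warn(f"{values.size - defined.size} label(s) with undefined "
                      "AUC excluded from the mean", stacklevel=2)
    return float(defined.mean())


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """Per-positive (V10) and per-negative (V01) placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc_val = v10.mean()
    return auc_val, v10, v01


def delong_test(scores_a, scores_b, labels):
    """Paired two-sided DeLong test for the AUC difference of two classifiers.

    Both score vectors must be evaluated on the same samples (``labels``).
    Returns ``(auc_a, auc_b, z, p_value)``.  A degenerate variance (e.g.
    identical score vectors) yields z = 0, p = 1 with a warning.
    """
    labels = _check_binary(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    auc_a, v10_a, v01_a = _structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _structural_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0 or not np.isfinite(var_diff):
        if abs(auc_a - auc_b) > 0:
            warnings.warn("degenerate DeLong variance with unequal AUCs",
                          stacklevel=2)
        else:
            warnings.warn("degenerate DeLong variance; returning p = 1",
                          stacklevel=2)
        return float(auc_a), float(auc_b), 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)
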