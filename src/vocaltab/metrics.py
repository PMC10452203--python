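"""Evaluation metrics: ROC-AUC via rank statistics, thresholded precision/recall."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve: P(score_pos > score_neg) + 0.5 P(tie).

    Computed from the Mann-Whitney rank-sum, with midranks for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC requires both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def precision_recall(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float]:
    """Precision and recall for the positive (PD = 1) class at a fixed threshold.

    If no sample scores above the threshold, precision is undefined; it is
    reported as 0 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0:
        raise ValueError("recall undefined without positive-class samples")
    pred = scores > threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    if tp + fp == 0:
        warnings.warn("no predicted positives; reporting precision 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(precision), float(recall)
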