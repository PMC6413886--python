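"""Benchmarking utilities: confusion statistics against gold-standard
rescuer sets, ROC / precision-recall analysis of interaction scores (lower
score = stronger predicted rescue), and Cohen's d effect sizes."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

__all__ = ["confusion_stats", "score_roc", "cohens_d"]


def confusion_stats(predicted, truth, universe_size: int):
    """Precision, recall, false-positive rate, and fold-over-chance of a
    predicted gene set against a gold-standard set.

    fold_over_chance uses the prevalence of the truth set in the universe
    as the chance baseline.  Empty predictions leave precision undefined
    (nan) with the other quantities still computed.
    """
    predicted, truth = set(predicted), set(truth)
    if universe_size < len(predicted | truth):
        raise ValueError("universe smaller than the union of the two sets")
    overlap = len(predicted & truth)
    precision = overlap / len(predicted) if predicted else float("nan")
    recall = overlap / len(truth) if truth else float("nan")
    negatives = universe_size - len(truth)
    fpr = len(predicted - truth) / negatives if negatives else float("nan")
    prevalence = len(truth) / universe_size
    fold = precision / prevalence if prevalence > 0 else float("nan")
    return precision, recall, fpr, fold


def score_roc(scores, labels):
    """ROC and precision-recall analysis of interaction scores.

    ``labels`` are 1 for true (positive) pairs; LOWER scores mean stronger
    predicted interactions, so ranking uses the negated score.  Returns
    (auc, (fpr, tpr, roc_thresholds), (precision, recall, pr_thresholds)).
    """
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("need both positive and negative labels")
    evidence = -scores
    auc = float(roc_auc_score(labels, evidence))
    roc_pts = roc_curve(labels, evidence)
    pr_pts = precision_recall_curve(labels, evidence)
    return auc, roc_pts, pr_pts


def cohens_d(x1, x2) -> float:
    """Difference of means over the pooled standard deviation
    sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))."""
    x1 = np.asarray(list(x1), dtype=float)
    x2 = np.asarray(list(x2), dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    s1, s2 = x1.var(ddof=1), x2.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x1.mean() - x2.mean()) / pooled)
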