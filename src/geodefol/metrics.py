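"""Classification performance measures on the infested/healthy confusion matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ClassificationMetrics:
    """Percent-scale confusion-matrix measures.

    F1 = 2 * sensitivity * precision / (sensitivity + precision).
    """

    sensitivity: float
    specificity: float
    precision: float
    overall: float
    f1: float
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0


def f1_from(sensitivity: float, precision: float) -> float:
    """Harmonic combination 2*S*P/(S+P) of percent sensitivity and precision."""
    if sensitivity < 0 or precision < 0:
        raise ValueError("sensitivity and precision must be >= 0")
    if sensitivity + precision == 0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def confusion_metrics(truth, predicted, positive="infested") -> ClassificationMetrics:
    """Sensitivity / specificity / precision / overall accuracy / F1 (in %).

    ``truth`` must contain both classes; sensitivity is the fraction of
    truly infested objects recovered, precision the fraction of predicted
    infested objects that are truly infested.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0:
        raise ValueError("empty label vectors")
    if truth.shape != predicted.shape:
        raise ValueError("label vectors differ in length")
    t = truth == positive
    p = predicted == positive
    if t.all() or (~t).all():
        raise ValueError("truth must contain both classes")
    tp = int((t & p).sum())
    fn = int((t & ~p).sum())
    tn = int((~t & ~p).sum())
    fp = int((~t & p).sum())
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    overall = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    f1 = 2 * sens * prec / (sens + prec) if sens + prec > 0 else 0.0
    return ClassificationMetrics(sens, spec, prec, overall, f1, tp, fn, tn, fp)


def roc_auc(truth, scores, positive="infested") -> float:
    """Area under the ROC curve, Mann–Whitney form.

    Equals P(score+ > score-) + 0.5 * P(tie) over all positive/negative
    pairs; computed from midranks so ties are handled exactly.
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    pos = truth == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC area")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size)
    sorted_scores = scores[order]
    i = 0
    r = np.arange(1, scores.size + 1, dtype=float)
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = r[i : j + 1].mean()  # midrank for ties
        i = j + 1
    rank_sum = ranks[pos].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
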