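"""Multi-label ranking and classification metrics.

Coverage and ranking loss operate on the real-valued score table; macro-F1
and accuracy operate on the derived binary relevant-label sets.  Rank ties
are broken by stable class order, and in ranking loss a tie between a
positive and a negative label counts as a reversal (``score(c+) <=
score(c-)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("smcc")

__all__ = [
    "EvaluationResult",
    "coverage",
    "ranking_loss",
    "macro_f1",
    "accuracy",
    "evaluate",
]


def _check(scores, truth):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same shape")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return scores, truth.astype(bool)


def coverage(scores, truth):
    """Mean depth (0-based) in each node's label ranking needed to cover all
    its true labels: ``(1/N) sum_i [max_{c in Y_i} rank(x_i, c) - 1]``."""
    scores, truth = _check(scores, truth)
    if (truth.sum(axis=1) < 1).any():
        raise ValueError("every truth row needs at least one positive label")
    n, k = scores.shape
    total = 0.0
    for i in range(n):
        order = np.argsort(-scores[i], kind="stable")
        ranks = np.empty(k, dtype=int)
        ranks[order] = np.arange(1, k + 1)
        total += ranks[truth[i]].max() - 1
    return float(total / n)


def ranking_loss(scores, truth):
    """Mean fraction of (positive, negative) label pairs ranked in the wrong
    order (ties count as reversals); rows without negatives are skipped."""
    scores, truth = _check(scores, truth)
    if (truth.sum(axis=1) < 1).any():
        raise ValueError("every truth row needs at least one positive label")
    losses = []
    skipped = 0
    for s, y in zip(scores, truth):
        pos, neg = s[y], s[~y]
        if neg.size == 0:
            skipped += 1
            continue
        reversed_pairs = np.sum(pos[:, None] <= neg[None, :])
        losses.append(reversed_pairs / (pos.size * neg.size))
    if skipped:
        logger.info("ranking_loss: skipped %d row(s) with no negative labels", skipped)
    if not losses:
        raise ValueError("no rows with both positive and negative labels")
    return float(np.mean(losses))


def _per_label_pr(predicted, truth):
    predicted, truth = _check(predicted, truth)
    predicted = predicted.astype(bool)
    tp = (predicted & truth).sum(axis=0).astype(float)
    p_denom = predicted.sum(axis=0)
    r_denom = truth.sum(axis=0)
    prec = np.divide(tp, p_denom, out=np.zeros_like(tp), where=p_denom > 0)
    rec = np.divide(tp, r_denom, out=np.zeros_like(tp), where=r_denom > 0)
    return prec, rec


def macro_f1(predicted, truth):
    """Per-label F1 averaged over labels; a label with p + r = 0 contributes 0."""
    prec, rec = _per_label_pr(predicted, truth)
    denom = prec + rec
    f1 = np.divide(2 * prec * rec, denom, out=np.zeros_like(prec), where=denom > 0)
    return float(f1.mean())


def accuracy(predicted, truth):
    """Single-label accuracy: fraction of nodes whose (unique) predicted label
    matches the (unique) true label."""
    predicted, truth = _check(predicted, truth)
    if (truth.sum(axis=1) != 1).any():
        raise ValueError("accuracy requires single-label truth (one positive per row)")
    return float(np.mean((predicted.astype(bool) == truth).all(axis=1)))


def top1_accuracy(scores, truth):
    """Fraction of nodes whose top-scoring label is the true label."""
    scores, truth = _check(scores, truth)
    if (truth.sum(axis=1) != 1).any():
        raise ValueError("accuracy requires single-label truth (one positive per row)")
    top = scores.argmax(axis=1)
    return float(np.mean(truth[np.arange(len(top)), top]))


@dataclass
class EvaluationResult:
    coverage: float
    ranking_loss: float
    macro_f1: float
    accuracy: float | None
    per_label_precision_recall: list


def evaluate(scores, predicted_sets, truth, class_names=None) -> EvaluationResult:
    """Compute the full metric panel on (typically) the unlabeled test nodes.

    ``predicted_sets`` is the binary relevant-label matrix; accuracy is
    reported only when the truth is single-label.
    """
    scores, truth_b = _check(scores, truth)
    prec, rec = _per_label_pr(predicted_sets, truth)
    acc = None
    if (truth_b.sum(axis=1) == 1).all():
        acc = top1_accuracy(scores, truth)
    return EvaluationResult(
        coverage=coverage(scores, truth),
        ranking_loss=ranking_loss(scores, truth),
        macro_f1=macro_f1(predicted_sets, truth),
        accuracy=acc,
        per_label_precision_recall=list(zip(prec.tolist(), rec.tolist())),
    )
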