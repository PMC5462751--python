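"""Ranking metrics for heavily imbalanced variant scoring.

Under extreme imbalance the area under the precision-recall curve (AUPRC)
is far more informative than the AUROC: a scorer can reach AUROC near 1
while burying every true positive below thousands of false positives.  The
module therefore centres on AUPRC (non-interpolated average precision),
with AUROC, precision/recall/F1 as functions of the score threshold, and
sensitivity as a function of the top-ranked quantile as companions.

Conventions: ranking uses a stable descending sort of the scores, so tied
scores keep their input order; AUROC gives exact half credit to
positive-negative score ties (the Mann-Whitney convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "auprc",
    "auroc",
    "prf_vs_threshold",
    "sensitivity_vs_quantile",
    "pr_curve",
    "plot_pr_curve",
]


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels.astype(int)


def _require_both_classes(labels):
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("metric undefined for single-class input")


def _descending_order(scores: np.ndarray) -> np.ndarray:
    # stable: ties keep input order
    return np.argsort(-scores, kind="stable")


def auprc(scores, labels) -> float:
    """Non-interpolated average precision.

    Walk the ranking by descending score; at the rank of every positive,
    record the precision among the variants ranked so far; average those
    precisions over the positives.
    """
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    ranked = labels[_descending_order(scores)]
    cum_pos = np.cumsum(ranked)
    ranks = np.arange(1, len(ranked) + 1)
    at_pos = ranked == 1
    return float(np.mean(cum_pos[at_pos] / ranks[at_pos]))


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)  # average ranks give exact tie credit
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def prf_vs_threshold(scores, labels, thresholds) -> pd.DataFrame:
    """Precision, recall and F1 of the rule ``score >= t`` for each threshold.

    When no variant is predicted positive, precision is reported as 1.0 and
    flagged in the ``no_predictions`` column (no false positives were made,
    but the value is vacuous).
    """
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    thresholds = np.asarray(thresholds, dtype=float).ravel()
    rows = []
    n_pos = labels.sum()
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        n_pred = int(pred.sum())
        no_pred = n_pred == 0
        precision = 1.0 if no_pred else tp / n_pred
        recall = tp / n_pos
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        rows.append((t, precision, recall, f1, no_pred))
    return pd.DataFrame(rows, columns=["threshold", "precision", "recall", "f1", "no_predictions"])


def sensitivity_vs_quantile(scores, labels, quantiles) -> pd.DataFrame:
    """Fraction of positives found in the top ``q`` quantile of the ranking.

    For each ``q`` in (0, 1], take the top ``ceil(q * T)`` variants by score
    (T = total variants) and report the fraction of all positives among
    them.  A sensitivity of 0.1 at q = 1e-3 means one tenth of the positives
    rank within the top thousandth of all variants.
    """
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    quantiles = np.asarray(quantiles, dtype=float).ravel()
    if ((quantiles <= 0) | (quantiles > 1)).any():
        raise ValueError("quantiles must lie in (0, 1]")
    ranked = labels[_descending_order(scores)]
    cum_pos = np.cumsum(ranked)
    n_pos = labels.sum()
    T = len(labels)
    tops = np.ceil(quantiles * T).astype(int)
    sens = cum_pos[tops - 1] / n_pos
    return pd.DataFrame({"quantile": quantiles, "sensitivity": sens})


def pr_curve(scores, labels) -> pd.DataFrame:
    """Precision-recall points swept over the full ranking."""
    scores, labels = _validate(scores, labels)
    _require_both_classes(labels)
    order = _descending_order(scores)
    ranked = labels[order]
    cum_pos = np.cumsum(ranked)
    ranks = np.arange(1, len(ranked) + 1)
    return pd.DataFrame(
        {
            "score": scores[order],
            "precision": cum_pos / ranks,
            "recall": cum_pos / labels.sum(),
        }
    )


def plot_pr_curve(scores, labels, path, title: str | None = None) -> None:
    """Write a PR-curve figure annotated with the AUPRC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curve = pr_curve(scores, labels)
    ap = auprc(scores, labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["recall"], curve["precision"], lw=1.5, label=f"AUPRC = {ap:.4f}")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
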