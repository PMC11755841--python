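"""Ranking and importance-recovery metrics.

Four quantities summarise a fitted recommender on labelled cells:

* Spearman's rho between true and fitted feature-importance scores;
* AUC — probability that a positive cell outscores a negative one (ties
  get half credit), evaluated on the labelled (nonzero) cells under
  consideration: unknown cells are unknown, not negatives;
* NS-AUC — user-averaged fraction of correctly ordered item pairs among
  pairs whose ground-truth labels strictly differ; ties in the scores earn
  no credit (strict inequality);
* NDCG at the list length — user-averaged discounted cumulative gain of
  the score-ranked item list over the top min(n, #positives) positions,
  normalised by the ideal gain. Gains are the raw labels, so a user whose
  top-ranked items are all negatives can score below zero.

Metrics that are undefined on the given input (single-class AUC, constant
Spearman input, no user with ordered pairs) are reported as NaN with a
warning rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricsReport",
    "spearman_rho",
    "auc",
    "ns_auc",
    "ndcg_at_ni",
    "evaluate_predictions",
]


@dataclass
class MetricsReport:
    auc: float
    ns_auc: float
    ndcg: float
    spearman_rho: float
    n_evaluated_pairs: int

    def to_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "ns_auc": self.ns_auc,
            "ndcg": self.ndcg,
            "spearman_rho": self.spearman_rho,
            "n_evaluated_pairs": self.n_evaluated_pairs,
        }


def spearman_rho(s_true, s_pred) -> float:
    """Rank correlation with average ranks on ties; NaN if an input is constant."""
    s_true = np.asarray(s_true, dtype=float)
    s_pred = np.asarray(s_pred, dtype=float)
    if s_true.shape != s_pred.shape or s_true.ndim != 1:
        raise ValueError("importance vectors must be 1-D and of equal length")
    if s_true.size < 2:
        raise ValueError("need at least two features")
    if np.all(s_true == s_true[0]) or np.all(s_pred == s_pred[0]):
        warnings.warn("constant importance vector: Spearman's rho undefined", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(s_true, s_pred).statistic)


def auc(labels, scores) -> float:
    """ROC area on +/-1 labelled cells; NaN (warned) on single-class input."""
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    if len(np.unique(labels[labels != 0])) < 2:
        warnings.warn("AUC undefined: only one class present", stacklevel=2)
        return float("nan")
    keep = labels != 0
    return float(roc_auc_score(labels[keep] == 1, scores[keep]))


def _count_ordered(hi: np.ndarray, lo: np.ndarray) -> tuple[int, int]:
    """(#pairs with hi_score > lo_score strictly, #pairs) between two groups."""
    lo_sorted = np.sort(lo)
    wins = int(np.searchsorted(lo_sorted, hi, side="left").sum())
    return wins, hi.size * lo.size


def ns_auc(A, scores, mask=None) -> float:
    """User-averaged fraction of correctly ordered item pairs.

    For each user, pairs (i, i') with A_{i,u} > A_{i',u} among the cells
    selected by ``mask`` (default: all cells, zeros included as the middle
    label) count as correct only when score_i > score_{i'} strictly.
    Users without any ordered pair are excluded from the average.
    """
    A = np.asarray(A)
    scores = np.asarray(scores, dtype=float)
    if A.shape != scores.shape:
        raise ValueError("A and scores must have equal shapes")
    mask = np.ones(A.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    per_user = []
    for u in range(A.shape[1]):
        rows = np.where(mask[:, u])[0]
        a, s = A[rows, u], scores[rows, u]
        wins = pairs = 0
        for hi_label, lo_label in ((1, 0), (1, -1), (0, -1)):
            hi, lo = s[a == hi_label], s[a == lo_label]
            if hi.size and lo.size:
                dw, dp = _count_ordered(hi, lo)
                wins, pairs = wins + dw, pairs + dp
        if pairs:
            per_user.append(wins / pairs)
    if not per_user:
        warnings.warn("NS-AUC undefined: no user with ordered pairs", stacklevel=2)
        return float("nan")
    return float(np.mean(per_user))


def ndcg_at_ni(A, scores, mask=None) -> float:
    """User-averaged NDCG over the top min(n, #positives) ranks, raw gains.

    Users without a positive cell are excluded. Because the gains are the
    raw labels in {-1, 0, +1}, the result can be negative when negatives
    rank on top.
    """
    A = np.asarray(A)
    scores = np.asarray(scores, dtype=float)
    if A.shape != scores.shape:
        raise ValueError("A and scores must have equal shapes")
    mask = np.ones(A.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    per_user = []
    for u in range(A.shape[1]):
        rows = np.where(mask[:, u])[0]
        a, s = A[rows, u], scores[rows, u]
        n_pos = int((a == 1).sum())
        if n_pos == 0:
            continue
        n_top = min(len(rows), n_pos)
        order = np.argsort(-s, kind="stable")
        discounts = 1.0 / np.log2(np.arange(2, n_top + 2))
        dcg = float(a[order[:n_top]] @ discounts)
        per_user.append(dcg / discounts.sum())
    if not per_user:
        warnings.warn("NDCG undefined: no user with a positive cell", stacklevel=2)
        return float("nan")
    return float(np.mean(per_user))


def evaluate_predictions(A, scores, mask=None, rank_mask=None,
                         s_true=None, s_pred=None) -> MetricsReport:
    """Bundle the four metrics for one prediction matrix.

    ``mask`` restricts the cells the AUC sees (e.g. a held-out split of the
    labelled cells; zeros are additionally dropped as unknown). The two
    ranking metrics run per user over the cells in ``rank_mask`` — the
    candidate list; in a split evaluation this is everything except the
    training cells, so held-out positives compete with the unknown cells
    (which act as the middle label). The Spearman term is NaN unless both
    importance vectors are supplied.
    """
    A = np.asarray(A)
    scores = np.asarray(scores, dtype=float)
    mask = np.ones(A.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    labels = A[mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = (
            spearman_rho(s_true, s_pred)
            if s_true is not None and s_pred is not None
            else float("nan")
        )
        return MetricsReport(
            auc=auc(labels, scores[mask]),
            ns_auc=ns_auc(A, scores, rank_mask),
            ndcg=ndcg_at_ni(A, scores, rank_mask),
            spearman_rho=rho,
            n_evaluated_pairs=int(mask.sum()),
        )
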