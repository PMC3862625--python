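"""Retrieval and diagnostic evaluation protocol.

Leave-one-out retrieval ranks all other samples by Euclidean distance to
a query in the embedding.  From the rankings the module computes

* AP@N / MAP@N over one query per category,
* the KNN positive score k+/k and its ROC curve / area (the area equals
  the normalized Mann-Whitney U statistic),
* a diagnostic test (majority of positives among the top k ranked images,
  k=15 by default) summarized as a TP/FP/FN/TN contingency table with
  sensitivity, specificity, diagnostic odds ratio with a Woolf log-normal
  95% CI, and F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RankedRetrieval",
    "ContingencyTable",
    "rank_retrieve",
    "average_precision_at_n",
    "map_at_n",
    "knn_positive_score",
    "roc_curve",
    "diagnostic_test",
    "sensitivity",
    "specificity",
    "dor",
    "dor_ci95",
    "f1",
]


@dataclass(frozen=True)
class RankedRetrieval:
    query: int
    ranking: np.ndarray  # all non-query indices by ascending distance
    distances: np.ndarray  # distances aligned with ranking
    metric: str = "l2"


@dataclass(frozen=True)
class ContingencyTable:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("contingency counts must be nonnegative")

    def with_continuity(self, add: float = 0.5) -> "np.ndarray":
        """Haldane-corrected cell values as floats (TP, FP, FN, TN)."""
        return np.array([self.TP, self.FP, self.FN, self.TN], dtype=float) + add


def rank_retrieve(embedding: np.ndarray, query: int) -> RankedRetrieval:
    """All other samples by ascending Euclidean distance (ties -> lower index)."""
    y = np.asarray(embedding, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to rank")
    d = np.linalg.norm(y - y[query], axis=1)
    d[query] = np.inf
    order = np.argsort(d, kind="stable")[: n - 1]
    return RankedRetrieval(query=query, ranking=order, distances=d[order])


def average_precision_at_n(
    relevance: Sequence[int], n: int, total_relevant: int
) -> float:
    """AP@N = sum_{j<=N} rel_j * Precision@j / min(R, N)."""
    if n < 1:
        raise ValueError("cutoff N must be >= 1")
    rel = np.asarray(relevance, dtype=bool)
    if n > rel.size:
        warnings.warn(
            f"cutoff N={n} exceeds ranking length {rel.size}; using full list",
            stacklevel=2,
        )
        n = rel.size
    top = rel[:n]
    if not top.any():
        return 0.0
    hits = np.cumsum(top)
    prec_at_hit = hits[top] / (np.flatnonzero(top) + 1)
    return float(prec_at_hit.sum() / min(total_relevant, n))


def map_at_n(
    embedding: np.ndarray,
    labels: np.ndarray,
    n: int,
    query_policy: str = "first",
    seed: int | None = None,
) -> float:
    """Mean AP@N over exactly one query per category.

    ``query_policy`` is ``"first"`` (lowest index per category, the
    default) or ``"random"`` (seeded draw per category).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    aps = []
    for cat in np.unique(labels):
        members = np.flatnonzero(labels == cat)
        if query_policy == "first":
            q = int(members[0])
        elif query_policy == "random":
            q = int(rng.choice(members))
        else:
            raise ValueError(f"unknown query_policy {query_policy!r}")
        ranked = rank_retrieve(embedding, q)
        rel = labels[ranked.ranking] == cat
        aps.append(average_precision_at_n(rel, n, int(members.size - 1)))
    return float(np.mean(aps))


def knn_positive_score(
    embedding: np.ndarray, index: int, positive: np.ndarray, k: int = 15
) -> float:
    """Fraction of positives among the k nearest non-query samples."""
    positive = np.asarray(positive, dtype=bool)
    if k > positive.size - 1:
        raise ValueError(f"k={k} exceeds N-1={positive.size - 1}")
    ranked = rank_retrieve(embedding, index)
    return float(positive[ranked.ranking[:k]].mean())


def roc_curve(
    scores: np.ndarray, positive: np.ndarray
) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC points and trapezoidal area.

    Predicts positive when score >= threshold, sweeping the unique score
    values from high to low; points run from (0, 0) to (1, 1).  The area
    equals the normalized Mann-Whitney U statistic (ties counted 1/2).
    """
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(positive, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    points = [(0.0, 0.0)]
    for thr in np.unique(s)[::-1]:
        pred = s >= thr
        tpr = (pred & pos).sum() / n_pos
        fpr = (pred & ~pos).sum() / n_neg
        points.append((float(fpr), float(tpr)))
    pts = np.array(points)
    area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, area


def diagnostic_test(
    embedding: np.ndarray,
    positive_indices: np.ndarray,
    negative_indices: np.ndarray,
    positive_class: np.ndarray,
    k: int = 15,
) -> ContingencyTable:
    """Majority-vote diagnostic test over leave-one-out rankings.

    Each test image (from the disjoint positive and negative test sets)
    is ranked against *all* other samples in the collection; it is called
    positive iff strictly more than k/2 of its top-k ranked samples
    belong to the positive class (for k=15: at least 8).
    """
    pos_idx = np.asarray(positive_indices)
    neg_idx = np.asarray(negative_indices)
    if np.intersect1d(pos_idx, neg_idx).size:
        raise ValueError("positive and negative test sets must be disjoint")
    positive_class = np.asarray(positive_class, dtype=bool)
    tp = fp = fn = tn = 0
    for idx, truth in [(i, True) for i in pos_idx] + [(i, False) for i in neg_idx]:
        ranked = rank_retrieve(embedding, int(idx))
        votes = int(positive_class[ranked.ranking[:k]].sum())
        called_positive = votes > k / 2
        if truth and called_positive:
            tp += 1
        elif truth:
            fn += 1
        elif called_positive:
            fp += 1
        else:
            tn += 1
    return ContingencyTable(TP=tp, FP=fp, FN=fn, TN=tn)


def sensitivity(t: ContingencyTable) -> float:
    """TP / (TP + FN)."""
    if t.TP + t.FN == 0:
        raise ZeroDivisionError("no positives in the test set")
    return t.TP / (t.TP + t.FN)


def specificity(t: ContingencyTable) -> float:
    """TN / (TN + FP)."""
    if t.TN + t.FP == 0:
        raise ZeroDivisionError("no negatives in the test set")
    return t.TN / (t.TN + t.FP)


def dor(t: ContingencyTable, continuity: bool = False) -> float:
    """Diagnostic odds ratio (TP*TN) / (FP*FN).

    Zero FP or FN cells make the ratio undefined; pass ``continuity=True``
    for the Haldane +0.5 correction on every cell.
    """
    tp, fp, fn, tn = (
        t.with_continuity() if continuity else (t.TP, t.FP, t.FN, t.TN)
    )
    if fp == 0 or fn == 0:
        raise ZeroDivisionError(
            "DOR undefined with an empty FP or FN cell; use continuity=True"
        )
    return (tp * tn) / (fp * fn)


def dor_ci95(t: ContingencyTable, continuity: bool = False) -> tuple[float, float]:
    """Woolf log-normal 95% confidence interval for the DOR."""
    tp, fp, fn, tn = (
        t.with_continuity() if continuity else (t.TP, t.FP, t.FN, t.TN)
    )
    if min(tp, fp, fn, tn) == 0:
        raise ZeroDivisionError("CI undefined with an empty cell; use continuity=True")
    log_dor = np.log((tp * tn) / (fp * fn))
    se = np.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    return float(np.exp(log_dor - 1.96 * se)), float(np.exp(log_dor + 1.96 * se))


def f1(t: ContingencyTable) -> float:
    """F1 = 2TP / (2TP + FP + FN)."""
    denom = 2 * t.TP + t.FP + t.FN
    if denom == 0:
        raise ZeroDivisionError("F1 undefined: no positives predicted or present")
    return 2 * t.TP / denom
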