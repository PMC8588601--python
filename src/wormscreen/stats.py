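"""Statistical tests and retrieval metrics used across the pipeline.

Thin, contract-checked wrappers around scipy/sklearn: two-sided Fisher
exact test (point-probability convention), one-tailed Wilcoxon rank-sum,
ROC/AUC and precision-recall/average precision, plus small group-summary
helpers for report tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.metrics import precision_recall_curve, roc_curve


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 group-by-outcome table.

    Rows are groups, columns are (positive, negative):
    ``[[a, b], [c, d]]``.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError(f"counts must be nonnegative integers, got {counts}")
        if sum(counts) == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class ScoredLabels:
    """Scores with binary labels (1 = positive) for ROC / PR curves."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        if not np.isin(labels, [0, 1]).all():
            raise ValueError("labels must be binary (0/1)")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(int))

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((1 - self.labels).sum())


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the point-probability ("Fisher") definition: the p-value is the
    sum of the probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed that of the observed table.

    A table with a zero margin carries no information about association;
    the degenerate p-value 1.0 is returned with a warning.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("2x2 table has a zero margin; p = 1.0 is degenerate")
        return 1.0
    return float(scipy.stats.fisher_exact(arr, alternative="two-sided")[1])


# Exact enumeration is limited to small samples; beyond this the normal
# approximation with tie and continuity correction is used.
_EXACT_RANKSUM_LIMIT = 12


def wilcoxon_ranksum_one_tailed(x, y) -> float:
    """One-tailed Wilcoxon rank-sum p-value (alternative: x > y).

    Exact by permutation enumeration when ``len(x) + len(y) <= 12`` and
    there are no ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all values tied across both samples; p = 1.0")
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= _EXACT_RANKSUM_LIMIT and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="greater", method=method, use_continuity=True
    )
    return float(res.pvalue)


def roc_auc(sl: ScoredLabels) -> tuple[np.ndarray, float]:
    """ROC curve points and trapezoidal AUC.

    Equal scores are grouped into a single threshold step, which makes the
    AUC equal to the Mann-Whitney concordance probability with half credit
    for ties.

    Returns
    -------
    points : (n, 2) array of (false positive rate, true positive rate)
    auc : float
    """
    if sl.n_positive == 0 or sl.n_negative == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    fpr, tpr, _ = roc_curve(sl.labels, sl.scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(np.trapezoid(tpr, fpr))

def precision_recall(sl: ScoredLabels) -> tuple[np.ndarray, float]:
    """Precision-recall curve points and average precision.

    AP = sum over descending-score steps of (R_k - R_{k-1}) * P_k.

    Returns
    -------
    points : (n, 2) array of (recall, precision)
    ap : float
    """
    if sl.n_positive == 0 or sl.n_negative == 0:
        raise ValueError("PR requires at least one positive and one negative")
    precision, recall, _ = precision_recall_curve(sl.labels, sl.scores)
    # sklearn returns the curve from high recall to low; AP is the step sum.
    rec = recall[::-1]
    prec = precision[::-1]
    ap = float(np.sum(np.diff(rec, prepend=0.0) * prec))
    return np.column_stack([rec, prec]), ap


def group_summary(values_by_group: dict[str, np.ndarray]) -> "list[dict]":
    """Mean / SEM / n per group, for report tables."""
    rows = []
    for group, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append({"group": group, "n": int(v.size), "mean": float(v.mean()), "sem": sem})
    return rows
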