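"""ROC/AUC, AUPRC, thresholded confusion metrics, DeLong and t tests,
and replicate aggregation.

AUC is computed by the rank (Mann-Whitney) formulation and therefore equals
the fraction of (positive, negative) pairs ranked correctly, with half
credit for ties.  AUPRC is the area under the precision-recall step curve
swept over descending score thresholds (no interpolation beyond the step
convention, which avoids the optimism of trapezoidal PR areas).  The DeLong
test compares two correlated AUCs computed on the same samples via the
structural-components (placement-value) covariance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "MetricsReport",
    "DeLongResult",
    "ReplicateSummary",
    "roc_auc",
    "pr_auc",
    "roc_curve_points",
    "pr_curve_points",
    "threshold_metrics",
    "delong_test",
    "two_tailed_t_test",
    "summarize_replicates",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    return labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via ranks; ties get 0.5 credit."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """(recall, precision) at each distinct descending-score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("precision-recall needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    pred_pos = np.arange(1, y.size + 1)
    # last index of each tied block = the threshold "score >= s" operating point
    block_end = np.flatnonzero(np.diff(s, append=-np.inf) != 0)
    recall = tp[block_end] / n_pos
    precision = tp[block_end] / pred_pos[block_end]
    return pd.DataFrame(
        {"threshold": s[block_end], "recall": recall, "precision": precision}
    )


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the PR step curve: sum_k (R_k - R_{k-1}) * P_k."""
    curve = pr_curve_points(scores, labels)
    recall = curve["recall"].to_numpy()
    precision = curve["precision"].to_numpy()
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev) * precision).sum())


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """(fpr, tpr) at each distinct descending-score threshold, with the
    (0, 0) origin, for external plotting."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    block_end = np.flatnonzero(np.diff(s, append=-np.inf) != 0)
    return pd.DataFrame(
        {
            "threshold": np.concatenate([[np.inf], s[block_end]]),
            "fpr": np.concatenate([[0.0], fp[block_end] / n_neg]),
            "tpr": np.concatenate([[0.0], tp[block_end] / n_pos]),
        }
    )


@dataclass
class MetricsReport:
    """Ranking and thresholded metrics for one model on one split.

    ``flags`` records degenerate conventions that fired (e.g. precision set
    to 0 because no sample was predicted positive).  ``auc``/``auprc`` are
    NaN when the split contains a single class.
    """

    auc: float
    auprc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float
    n_pos: int
    n_neg: int
    flags: tuple[str, ...] = ()

    METRIC_NAMES = ("auc", "auprc", "accuracy", "precision", "recall", "f1")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auprc": self.auprc,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "threshold": self.threshold,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "flags": list(self.flags),
        }


def threshold_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.3
) -> MetricsReport:
    """Confusion-matrix metrics predicting positive iff score >= threshold.

    Precision and F1 are defined as 0 (and flagged) when no positives are
    predicted; recall is 0 (flagged) when the split has no positives, in
    which case AUC/AUPRC are NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pred = scores >= threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    n = labels.size
    flags: list[str] = []

    accuracy = (tp + tn) / n
    if tp + fp == 0:
        precision = 0.0
        flags.append("no_predicted_positives")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        flags.append("no_positives_in_labels")
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)

    n_pos, n_neg = tp + fn, fp + tn
    if n_pos and n_neg:
        auc = roc_auc(scores, labels)
        auprc = pr_auc(scores, labels)
    else:
        auc = auprc = float("nan")
    return MetricsReport(
        auc=auc,
        auprc=auprc,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        threshold=threshold,
        n_pos=n_pos,
        n_neg=n_neg,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUCs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    variance_of_delta: float
    z: float
    p_two_sided: float


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative), and the AUC.

    V10_i = fraction of negatives ranked below positive i (ties half);
    V01_j = fraction of positives ranked above negative j (ties half).
    Computed with midranks in O(n log n).
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> DeLongResult:
    """DeLong's test for the difference of two correlated AUCs.

    Both score vectors must be paired on the same samples.  The variance of
    the AUC difference comes from the empirical covariance of the placement
    values; the p-value is two-sided normal.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_binary(labels)
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ValueError("scores and labels must have identical length")
    m = int(labels.sum())
    n = labels.size - m
    if m == 0 or n == 0:
        raise ValueError("DeLong test needs both classes present")

    v10_a, v01_a, auc_a = _placements(scores_a, labels)
    v10_b, v01_b, auc_b = _placements(scores_b, labels)
    delta = auc_a - auc_b

    if m > 1 and n > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n
    else:
        var = 0.0
    var = max(var, 0.0)

    if var > 0:
        z = delta / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z = 0.0 if delta == 0 else np.inf * np.sign(delta)
        p = 1.0 if delta == 0 else 0.0
    return DeLongResult(auc_a, auc_b, float(delta), float(var), float(z), float(p))


def two_tailed_t_test(
    values_a: np.ndarray, values_b: np.ndarray, equal_var: bool = False
) -> float:
    """Two-sided two-sample t-test p-value; Welch form by default.

    Both groups flat with equal means gives p = 1; both flat with different
    means gives p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


@dataclass
class ReplicateSummary:
    """Per-metric mean and sample (n-1) standard deviation over replicates."""

    stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_replicates: int = 0

    def formatted(self, metric: str, decimals: int = 3) -> str:
        mean, sd = self.stats[metric]
        return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            **{
                name: {"mean": mean, "sd": sd, "formatted": self.formatted(name)}
                for name, (mean, sd) in self.stats.items()
            },
        }


def summarize_replicates(reports: list[MetricsReport]) -> ReplicateSummary:
    """Mean +/- sample sd of each metric over replicate runs."""
    if not reports:
        raise ValueError("no replicate reports to summarize")
    out: dict[str, tuple[float, float]] = {}
    for name in MetricsReport.METRIC_NAMES:
        values = np.array([getattr(r, name) for r in reports], dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        out[name] = (mean, sd)
    return ReplicateSummary(out, len(reports))
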