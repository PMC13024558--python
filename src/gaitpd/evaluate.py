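"""Classification metrics, repeat aggregation, and paired model comparison.

AUC is computed in the rank (Mann-Whitney probability) form with ties
counting one half.  Repeats over subject-wise splits are summarized as
mean, sample SD, and an empirical 95% CI from a percentile bootstrap of the
mean.  Models are compared split-by-split with an exact paired Wilcoxon
signed-rank test — exact because with five repeats the normal approximation
is meaningless, and at n = 5 the smallest attainable two-sided p is 0.0625,
a fact the report surfaces rather than hides.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_THRESHOLD = 0.5


def window_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney probability form of ROC-AUC; ties count 1/2."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = sps.rankdata(probabilities)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


@dataclasses.dataclass
class MetricSet:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    level: str  # "window" or "subject"


def compute_metrics(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    level: str = "window",
) -> MetricSet:
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = window_auc(probabilities, labels)
    pred = (probabilities >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return MetricSet(
        auc=auc,
        accuracy=(tp + tn) / labels.size,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        threshold=threshold,
        level=level,
    )


def confusion_matrix(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """2x2 table (rows: actual CO/PD, columns: predicted CO/PD)."""
    pred = (np.asarray(probabilities) >= threshold).astype(int)
    labels = np.asarray(labels, dtype=int)
    mat = [
        [int(((labels == a) & (pred == p)).sum()) for p in (0, 1)] for a in (0, 1)
    ]
    return pd.DataFrame(
        mat, index=["actual_CO", "actual_PD"], columns=["pred_CO", "pred_PD"]
    )


def subject_level(
    probabilities: np.ndarray, subject_ids: list[str], labels: np.ndarray
) -> pd.DataFrame:
    """Per-subject probability (mean of window probabilities) and label."""
    frame = pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "prob": np.asarray(probabilities, dtype=float),
            "label": np.asarray(labels, dtype=int),
        }
    )
    n_labels = frame.groupby("subject_id")["label"].nunique()
    if (n_labels > 1).any():
        bad = n_labels[n_labels > 1].index.tolist()
        raise ValueError(f"inconsistent labels within subject(s): {bad}")
    out = (
        frame.groupby("subject_id", sort=True)
        .agg(prob=("prob", "mean"), label=("label", "first"))
        .reset_index()
    )
    return out


@dataclasses.dataclass
class RepeatSummary:
    """Mean, sample SD, empirical 95% CI per metric, over repeated splits."""

    n_repeats: int
    metrics: dict[str, dict[str, float]]  # metric -> mean/sd/ci_lower/ci_upper


def _summarize_values(
    values: np.ndarray, n_boot: int = 10_000, seed: int = 0
) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    boots = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "ci_lower": float(lo),
        "ci_upper": float(hi),
    }


def aggregate_repeats(
    metric_sets: list[MetricSet], n_boot: int = 10_000, seed: int = 0
) -> RepeatSummary:
    """Summarize >= 2 repeated evaluations (percentile bootstrap of the mean)."""
    if len(metric_sets) < 2:
        raise ValueError("need >= 2 repeats to form SD and empirical CI")
    out = {}
    for name in ("auc", "accuracy", "sensitivity", "specificity"):
        values = np.array([getattr(m, name) for m in metric_sets])
        out[name] = _summarize_values(values, n_boot=n_boot, seed=seed)
    return RepeatSummary(n_repeats=len(metric_sets), metrics=out)


@dataclasses.dataclass
class WilcoxonResult:
    statistic: float        # W+ = sum of ranks of positive differences
    p_one_sided: float      # alternative: A > B
    p_two_sided: float
    n_effective: int        # pairs remaining after dropping zero differences


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign patterns by doubled W+ (generating-function dp)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


EXACT_WILCOXON_MAX_N = 25


def paired_wilcoxon(values_a: np.ndarray, values_b: np.ndarray) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test, exact for n <= 25.

    Zero differences are dropped; tied |differences| get average ranks
    (possibly half-integer, handled exactly by doubling).  Both one-sided
    (A > B) and two-sided p are reported.  All differences zero is the
    degenerate case p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d arrays (paired by split)")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_one_sided=1.0, p_two_sided=1.0, n_effective=0)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(doubled)
        total = counts.sum()  # 2**n
        w2 = int(round(2 * w_plus))
        p_ge = counts[w2:].sum() / total
        p_le = counts[: w2 + 1].sum() / total
        p_one = p_ge
        p_two = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        res_greater = sps.wilcoxon(a, b, alternative="greater", method="approx")
        res_two = sps.wilcoxon(a, b, alternative="two-sided", method="approx")
        p_one, p_two = float(res_greater.pvalue), float(res_two.pvalue)
    return WilcoxonResult(
        statistic=w_plus, p_one_sided=float(p_one), p_two_sided=float(p_two), n_effective=n
    )
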