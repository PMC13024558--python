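"""Data-level validation of consensus features.

Group differences on the raw (unnormalized, physical-unit) window features
are tested with the Mann-Whitney U test — exact enumeration when
min(n, m) <= 8, tie-corrected normal approximation otherwise — with Cliff's
delta as the effect size, oriented PD minus control (negative delta means
the PD group sits below the controls).  The Benjamini-Hochberg step-up
controls the FDR over the consensus feature family; alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
EXACT_MW_MAX = 8          # exact branch when min(n, m) <= this


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{x_i > y_j} + 0.5 * #{ties}, via pair comparison."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(x, y) -> tuple[float, float]:
    """(U, two-sided p).  Exact permutation null for small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    n, m = x.size, y.size
    if min(n, m) <= EXACT_MW_MAX and comb(n + m, n) <= 200_000:
        pooled = np.concatenate([x, y])
        n_total = n + m
        count_as_extreme = 0
        mu = n * m / 2.0
        observed_dev = abs(u - mu)
        for idx in combinations(range(n_total), n):
            xi = pooled[list(idx)]
            mask = np.ones(n_total, dtype=bool)
            mask[list(idx)] = False
            ui = _u_statistic(xi, pooled[mask])
            if abs(ui - mu) >= observed_dev - 1e-12:
                count_as_extreme += 1
        p = count_as_extreme / comb(n_total, n)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u, float(min(1.0, p))


def cliffs_delta(x, y) -> float:
    """delta = (#{x > y} - #{x < y}) / (n_x * n_y); x = PD, y = control."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float(((diff > 0).sum() - (diff < 0).sum()) / (x.size * y.size))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    """Median and IQR (Q3 - Q1) with linear-interpolation quantiles."""
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return float(q2), float(q3 - q1)


@dataclasses.dataclass
class BiomarkerResult:
    feature: str
    control_median: float
    control_iqr: float
    pd_median: float
    pd_iqr: float
    p_raw: float
    p_adjusted: float       # filled in after family-wise BH adjustment
    cliffs_delta: float     # PD - CO orientation


def summarize_feature(control_values, pd_values, feature: str = "") -> BiomarkerResult:
    """Single-feature group comparison; p_adjusted starts equal to p_raw."""
    control_values = np.asarray(control_values, dtype=float)
    pd_values = np.asarray(pd_values, dtype=float)
    c_med, c_iqr = _median_iqr(control_values)
    p_med, p_iqr = _median_iqr(pd_values)
    _, p_raw = mann_whitney_u(pd_values, control_values)
    delta = cliffs_delta(pd_values, control_values)
    return BiomarkerResult(
        feature=feature,
        control_median=c_med, control_iqr=c_iqr,
        pd_median=p_med, pd_iqr=p_iqr,
        p_raw=p_raw, p_adjusted=p_raw, cliffs_delta=delta,
    )


def validate_features(
    raw_frame: pd.DataFrame, features: list[str], by_subject: bool = False
) -> pd.DataFrame:
    """Group comparison table for a feature family, BH-adjusted within it.

    `raw_frame` is the flat raw-feature export (subject_id, label, 36
    columns in force units).  The test unit is the window by default;
    with by_subject=True, per-subject means are compared instead.
    """
    if by_subject:
        raw_frame = (
            raw_frame.groupby("subject_id", sort=True)
            .agg({**{f: "mean" for f in features}, "label": "first"})
            .reset_index()
        )
    results = []
    for feat in features:
        control = raw_frame.loc[raw_frame["label"] == 0, feat].to_numpy()
        pd_vals = raw_frame.loc[raw_frame["label"] == 1, feat].to_numpy()
        results.append(summarize_feature(control, pd_vals, feature=feat))
    if results:
        adjusted = bh_fdr([r.p_raw for r in results])
        for r, p_adj in zip(results, adjusted):
            r.p_adjusted = float(p_adj)
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
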