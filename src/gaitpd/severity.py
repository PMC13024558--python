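"""Stage 2: continuous Hoehn & Yahr severity regression at the subject level.

Each subject is summarized by 72 values — the across-window mean and
across-window std of each of the 36 raw token features — and a
gradient-boosted tree ensemble (XGBoost, squared-error objective) maps them
to a continuous H&Y stage.  Subject-wise segregation is enforced: any
overlap between training and test subjects aborts the run.  Performance is
reported as MAE, RMSE, R², and Spearman rank correlation, with Cohen's
f² = R²/(1-R²) and noncentral-F post hoc power quantifying whether the
sample size supports the observed explanatory power.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from xgboost import XGBRegressor

from .windowing import FEATURE_NAMES, TokenizedWindow

#: 72 subject-level column names: across-window mean and std of each feature
SUBJECT_FEATURE_NAMES: list[str] = [
    f"{f}_w{stat}" for f in FEATURE_NAMES for stat in ("mean", "std")
]


def subject_features(windows: list[TokenizedWindow]) -> np.ndarray:
    """Across-window mean and std of each raw feature; std 0 if one window.

    Order-invariant in the windows; returns a length-72 vector matching
    SUBJECT_FEATURE_NAMES.
    """
    if not windows:
        raise ValueError("subject has no windows")
    flat = np.array([w.raw_features.reshape(-1) for w in windows])  # (n, 36)
    means = flat.mean(axis=0)
    stds = flat.std(axis=0) if flat.shape[0] > 1 else np.zeros(flat.shape[1])
    return np.stack([means, stds], axis=1).reshape(-1)


def subject_feature_frame(
    windows_by_subject: dict[str, list[TokenizedWindow]],
    hy_by_subject: dict[str, float],
) -> pd.DataFrame:
    rows = []
    for sid in sorted(windows_by_subject):
        vec = subject_features(windows_by_subject[sid])
        row = {"subject_id": sid, "hy_stage": hy_by_subject[sid]}
        row.update(dict(zip(SUBJECT_FEATURE_NAMES, vec)))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SeverityModelConfig:
    n_estimators: int = 300
    max_depth: int = 3
    learning_rate: float = 0.05
    subsample: float = 0.9
    seed: int = 0


def train_severity_model(
    train_frame: pd.DataFrame,
    config: SeverityModelConfig | None = None,
    test_subjects: set[str] | None = None,
) -> XGBRegressor:
    """Fit the gradient-boosted regressor on subject-level vectors.

    If `test_subjects` is given, any overlap with the training subjects
    raises (leakage guard).
    """
    config = config or SeverityModelConfig()
    if len(train_frame) < 5:
        raise ValueError("need >= 5 training subjects")
    if test_subjects is not None:
        overlap = set(train_frame["subject_id"]) & set(test_subjects)
        if overlap:
            raise AssertionError(f"train/test subject overlap: {sorted(overlap)}")
    model = XGBRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        subsample=config.subsample,
        objective="reg:squarederror",
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(train_frame[SUBJECT_FEATURE_NAMES], train_frame["hy_stage"])
    return model


def regression_metrics(actual, predicted) -> dict[str, float]:
    """MAE, RMSE, R² about mean(actual), tie-corrected Spearman rho with p."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length 1-d arrays with >= 2 entries")
    if np.allclose(a, a[0]):
        raise ValueError("R² and Spearman rho undefined: actual has zero variance")
    residuals = a - p
    ss_res = float((residuals**2).sum())
    ss_tot = float(((a - a.mean()) ** 2).sum())
    rho, rho_p = sps.spearmanr(a, p)
    return {
        "mae": float(np.abs(residuals).mean()),
        "rmse": float(np.sqrt((residuals**2).mean())),
        "r2": 1.0 - ss_res / ss_tot,
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
    }


def effect_size_f2(r2: float) -> float:
    """Cohen's f² = R² / (1 - R²)."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    return r2 / (1.0 - r2)


def posthoc_power(
    f2: float, n_subjects: int, n_predictors: int, alpha: float = 0.05
) -> float:
    """Power of the regression F test at effect size f².

    Noncentral F with df (p, n - p - 1) and noncentrality lambda = f² * n
    (Cohen's convention); power = P(F' > F_crit) at the central-F critical
    value.  f² = 0 returns exactly alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if f2 < 0:
        raise ValueError("f2 must be >= 0")
    df1 = n_predictors
    df2 = n_subjects - n_predictors - 1
    if df1 < 1 or df2 < 1:
        raise ValueError("need n_subjects > n_predictors + 1")
    f_crit = sps.f.ppf(1.0 - alpha, df1, df2)
    if f2 == 0:
        return float(sps.f.sf(f_crit, df1, df2))  # = alpha by construction
    return float(sps.ncf.sf(f_crit, df1, df2, f2 * n_subjects))


@dataclasses.dataclass
class SeverityReport:
    """Per-subject actual vs predicted continuous H&Y plus summary metrics."""

    subjects: pd.DataFrame  # subject_id, actual, predicted, abs_difference
    mae: float
    rmse: float
    r2: float
    spearman_rho: float
    spearman_p: float
    f2: float
    power: float
    n_subjects: int
    n_predictors: int

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["subjects"] = self.subjects.to_dict(orient="records")
        return out


def severity_report(
    actual,
    predicted,
    subject_ids: list[str],
    n_predictors: int = len(SUBJECT_FEATURE_NAMES),
    alpha: float = 0.05,
) -> SeverityReport:
    metrics = regression_metrics(actual, predicted)
    f2 = effect_size_f2(max(0.0, metrics["r2"]))
    n = len(subject_ids)
    # power analysis needs positive residual df; cap predictors at the data
    k = min(n_predictors, max(1, n - 2))
    power = posthoc_power(f2, n, k, alpha=alpha)
    frame = pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "actual": np.asarray(actual, dtype=float),
            "predicted": np.asarray(predicted, dtype=float),
        }
    )
    frame["abs_difference"] = (frame["actual"] - frame["predicted"]).abs()
    return SeverityReport(
        subjects=frame,
        mae=metrics["mae"], rmse=metrics["rmse"], r2=metrics["r2"],
        spearman_rho=metrics["spearman_rho"], spearman_p=metrics["spearman_p"],
        f2=f2, power=power, n_subjects=n, n_predictors=k,
    )
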