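"""End-to-end orchestration: simulate -> windows -> stage-1 classification ->
stability-consensus XAI -> biomarker statistics -> stage-2 severity.

Every stage is callable on its own; `run_all` chains them and optionally
writes the plot-ready CSV/JSON artifacts.  All randomness descends from one
base seed: split k uses seed base_seed + k, and each (split, arch) training
run derives its init/shuffle seed from those, so a full run is reproducible
end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import AttributionRecord, aggregate_attributions
from .backbones import (
    ARCHS,
    ModelSpec,
    TrainedModel,
    TrainingConfig,
    build_model,
    train_classifier,
)
from .evaluate import (
    MetricSet,
    aggregate_repeats,
    compute_metrics,
    confusion_matrix,
    paired_wilcoxon,
    subject_level,
)
from .io import GaitSignal, read_demographics, read_vgrf_file, write_demographics, write_vgrf_file
from .severity import (
    SeverityModelConfig,
    SeverityReport,
    severity_report,
    subject_feature_frame,
    train_severity_model,
)
from .splits import SplitPlan, assert_no_leakage, make_repeated_splits
from .stability import stability_table
from .stats import validate_features
from .synth import CohortConfig, generate_cohort
from .windowing import (
    RecordTooShort,
    TokenizedWindow,
    WindowConfig,
    assert_stats_clean,
    feature_matrix,
    fit_channel_stats,
    labels_of,
    segment,
    tokenize,
    windows_to_frame,
)


@dataclasses.dataclass
class XAIConfig:
    top_fraction: float = 0.2
    consensus_threshold: float = 0.2
    n_steps: int = 50
    n_experiments_override: int | None = None  # defaults to n_splits * n_archs


@dataclasses.dataclass
class RunConfig:
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    window: WindowConfig = dataclasses.field(default_factory=WindowConfig)
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)
    n_repeats: int = 5
    base_seed: int = 0
    archs: tuple[str, ...] = ARCHS
    hidden: int = 32
    depth: int = 3
    dropout: float = 0.0
    heads: int = 4
    training: TrainingConfig = dataclasses.field(default_factory=TrainingConfig)
    xai: XAIConfig = dataclasses.field(default_factory=XAIConfig)
    alpha: float = 0.05
    severity: SeverityModelConfig = dataclasses.field(default_factory=SeverityModelConfig)
    stage2_mode: str = "inclusive"   # or "paper_literal"
    threshold: float = 0.5

    def model_spec(self, arch: str) -> ModelSpec:
        return ModelSpec(
            arch=arch, hidden=self.hidden, depth=self.depth,
            dropout=self.dropout, heads=self.heads,
        )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def derive_seed(*keys: int) -> int:
    """Stable sub-seed below 2**31 from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def simulate(config: RunConfig, out_dir: str | Path | None = None):
    """Generate the synthetic cohort; optionally write it in the text dialect."""
    signals, table, truths = generate_cohort(config.cohort)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sig in signals:
            write_vgrf_file(sig, out / f"{sig.subject_id}.txt")
        write_demographics(table, out / "demographics.csv")
        from .synth import truth_table

        truth_table(truths).to_csv(out / "truth.csv", index=False)
    return signals, table, truths


def load_cohort(data_dir: str | Path) -> tuple[list[GaitSignal], pd.DataFrame]:
    """Read a written cohort back through the I/O boundary."""
    data_dir = Path(data_dir)
    table = read_demographics(data_dir / "demographics.csv")
    signals = [
        read_vgrf_file(data_dir / f"{sid}.txt", subject_id=sid)
        for sid in table["subject_id"]
    ]
    return signals, table


def tokenize_split(
    signals: list[GaitSignal],
    table: pd.DataFrame,
    plan: SplitPlan,
    window_config: WindowConfig,
) -> dict[str, list[TokenizedWindow]]:
    """Windows per partition, z-scored with training-subject stats only."""
    labels = dict(zip(table["subject_id"], (table["group"] == "PD").astype(int)))
    by_partition: dict[str, list[GaitSignal]] = {"train": [], "val": [], "test": []}
    for sig in signals:
        by_partition[plan.assignment[sig.subject_id]].append(sig)
    stats = fit_channel_stats(by_partition["train"], epsilon=window_config.epsilon)
    assert_stats_clean(stats, set(plan.subjects("train")))
    out: dict[str, list[TokenizedWindow]] = {}
    for partition, part_signals in by_partition.items():
        windows: list[TokenizedWindow] = []
        for sig in part_signals:
            try:
                ranges = segment(sig, window_config)
            except RecordTooShort:
                warnings.warn(f"record {sig.subject_id} shorter than one window; skipped")
                continue
            windows.extend(
                tokenize(sig, ranges, stats, sig.subject_id, labels[sig.subject_id])
            )
        out[partition] = windows
    # hard leakage guard on the realized windows
    subj, parts = [], []
    for partition, windows in out.items():
        subj.extend(w.subject_id for w in windows)
        parts.extend([partition] * len(windows))
    assert_no_leakage(subj, parts, strict=True)
    return out


def tokenize_cohort_raw(
    signals: list[GaitSignal], table: pd.DataFrame, window_config: WindowConfig
) -> pd.DataFrame:
    """Raw-unit window features for the whole cohort (data-level statistics).

    Raw features are unaffected by normalization, so cohort-wide stats are
    safe here; model inputs never come from this path.
    """
    labels = dict(zip(table["subject_id"], (table["group"] == "PD").astype(int)))
    stats = fit_channel_stats(signals, epsilon=window_config.epsilon)
    windows: list[TokenizedWindow] = []
    for sig in signals:
        try:
            ranges = segment(sig, window_config)
        except RecordTooShort:
            continue
        windows.extend(tokenize(sig, ranges, stats, sig.subject_id, labels[sig.subject_id]))
    return windows_to_frame(windows, raw=True)


# ---------------------------------------------------------------------------
# stage 1: repeated subject-wise classification + attribution
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExperimentResult:
    arch: str
    split_seed: int
    trained: TrainedModel
    window_metrics: MetricSet
    subject_metrics: MetricSet
    subject_probs: pd.DataFrame
    confusion: pd.DataFrame
    attribution: AttributionRecord


@dataclasses.dataclass
class Stage1Result:
    plans: list[SplitPlan]
    experiments: list[ExperimentResult]
    summary: pd.DataFrame            # per arch: mean/SD/CI of the 4 metrics
    wilcoxon: pd.DataFrame           # all arch pairs, paired by split, on AUC
    split_windows: list[dict[str, list[TokenizedWindow]]]
    config_hash: str
    version: str = __version__

    def auc_values(self, arch: str) -> np.ndarray:
        return np.array(
            [e.window_metrics.auc for e in self.experiments if e.arch == arch]
        )


def run_stage1(
    config: RunConfig, signals: list[GaitSignal], table: pd.DataFrame
) -> Stage1Result:
    plans = make_repeated_splits(
        table, config.ratios, n_repeats=config.n_repeats, base_seed=config.base_seed
    )
    split_windows = [
        tokenize_split(signals, table, plan, config.window) for plan in plans
    ]
    experiments: list[ExperimentResult] = []
    for plan, windows in zip(plans, split_windows):
        X_test, y_test = feature_matrix(windows["test"]), labels_of(windows["test"])
        test_subjects = [w.subject_id for w in windows["test"]]
        for arch_idx, arch in enumerate(config.archs):
            seed = derive_seed(plan.seed, arch_idx)
            model = build_model(config.model_spec(arch), seed=seed)
            tcfg = dataclasses.replace(config.training, seed=seed)
            trained = train_classifier(model, windows["train"], windows["val"], tcfg)
            probs = trained.predict_proba(X_test)
            wm = compute_metrics(probs, y_test, config.threshold, level="window")
            subj = subject_level(probs, test_subjects, y_test)
            sm = compute_metrics(
                subj["prob"].to_numpy(), subj["label"].to_numpy(),
                config.threshold, level="subject",
            )
            record = aggregate_attributions(
                trained.model, X_test, n_steps=config.xai.n_steps,
                arch=arch, split_seed=plan.seed,
            )
            experiments.append(
                ExperimentResult(
                    arch=arch, split_seed=plan.seed, trained=trained,
                    window_metrics=wm, subject_metrics=sm, subject_probs=subj,
                    confusion=confusion_matrix(probs, y_test, config.threshold),
                    attribution=record,
                )
            )
    summary = _stage1_summary(config, experiments)
    wilcoxon = _arch_comparisons(config, experiments)
    return Stage1Result(
        plans=plans, experiments=experiments, summary=summary, wilcoxon=wilcoxon,
        split_windows=split_windows, config_hash=config.config_hash(),
    )


def _stage1_summary(config: RunConfig, experiments: list[ExperimentResult]) -> pd.DataFrame:
    rows = []
    for arch in config.archs:
        sets = [e.window_metrics for e in experiments if e.arch == arch]
        agg = aggregate_repeats(sets, seed=config.base_seed)
        row = {"arch": arch, "n_repeats": agg.n_repeats}
        for metric, vals in agg.metrics.items():
            for key, v in vals.items():
                row[f"{metric}_{key}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _arch_comparisons(config: RunConfig, experiments: list[ExperimentResult]) -> pd.DataFrame:
    rows = []
    archs = list(config.archs)
    aucs = {
        arch: np.array([e.window_metrics.auc for e in experiments if e.arch == arch])
        for arch in archs
    }
    for i, a in enumerate(archs):
        for b in archs[i + 1 :]:
            res = paired_wilcoxon(aucs[a], aucs[b])
            rows.append(
                {
                    "model_a": a, "model_b": b, "statistic": res.statistic,
                    "p_one_sided_a_gt_b": res.p_one_sided,
                    "p_two_sided": res.p_two_sided, "n_pairs": res.n_effective,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# XAI consensus + data-level statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class XAIResult:
    stability: pd.DataFrame
    consensus: list[str]
    biomarkers: pd.DataFrame


def run_xai(
    config: RunConfig,
    stage1: Stage1Result,
    signals: list[GaitSignal],
    table: pd.DataFrame,
) -> XAIResult:
    records = [e.attribution for e in stage1.experiments]
    stab = stability_table(
        records,
        fraction=config.xai.top_fraction,
        threshold=config.xai.consensus_threshold,
    )
    if config.xai.n_experiments_override is not None:
        n = config.xai.n_experiments_override
        stab["n_experiments"] = n
        stab["score"] = stab["count"] / n
        stab["consensus"] = stab["score"] >= config.xai.consensus_threshold
    consensus = (
        stab[stab["consensus"]]
        .sort_values(["score", "feature"], ascending=[False, True])["feature"]
        .tolist()
    )
    if not consensus:
        warnings.warn("no consensus features at the current threshold")
        return XAIResult(stability=stab, consensus=[], biomarkers=pd.DataFrame())
    raw = tokenize_cohort_raw(signals, table, config.window)
    biomarkers = validate_features(raw, consensus)
    return XAIResult(stability=stab, consensus=consensus, biomarkers=biomarkers)


# ---------------------------------------------------------------------------
# stage 2: severity regression
# ---------------------------------------------------------------------------

def run_stage2(
    config: RunConfig, stage1: Stage1Result, table: pd.DataFrame
) -> SeverityReport:
    """Held-out continuous H&Y prediction, pooled over the repeated splits.

    For each split a regressor is fitted on the train+val subjects (controls
    at stage 0) and predicts the test subjects; a subject predicted in
    several splits gets the mean of its held-out predictions.  In
    "paper_literal" mode only test subjects flagged PD by the best stage-1
    model of that split are evaluated; the default "inclusive" mode keeps
    all test subjects, matching a report that contains stage-0 rows.
    """
    hy = dict(zip(table["subject_id"], table["hy_stage"].astype(float)))
    best_arch = stage1.summary.sort_values("auc_mean", ascending=False)["arch"].iloc[0]
    pooled: dict[str, list[float]] = {}
    for plan, windows in zip(stage1.plans, stage1.split_windows):
        by_subject: dict[str, list[TokenizedWindow]] = {}
        for part in ("train", "val", "test"):
            for w in windows[part]:
                by_subject.setdefault(w.subject_id, []).append(w)
        train_ids = sorted(
            set(plan.subjects("train")) | set(plan.subjects("val"))
        )
        test_ids = sorted(plan.subjects("test"))
        if config.stage2_mode == "paper_literal":
            exp = next(
                e for e in stage1.experiments
                if e.arch == best_arch and e.split_seed == plan.seed
            )
            flagged = set(
                exp.subject_probs.loc[
                    exp.subject_probs["prob"] >= config.threshold, "subject_id"
                ]
            )
            test_ids = [s for s in test_ids if s in flagged]
        train_frame = subject_feature_frame(
            {s: by_subject[s] for s in train_ids if s in by_subject}, hy
        )
        test_frame = subject_feature_frame(
            {s: by_subject[s] for s in test_ids if s in by_subject}, hy
        )
        if test_frame.empty:
            continue
        scfg = dataclasses.replace(config.severity, seed=derive_seed(config.base_seed, plan.seed))
        model = train_severity_model(
            train_frame, scfg, test_subjects=set(test_frame["subject_id"])
        )
        from .severity import SUBJECT_FEATURE_NAMES

        preds = model.predict(test_frame[SUBJECT_FEATURE_NAMES])
        for sid, p in zip(test_frame["subject_id"], preds):
            pooled.setdefault(sid, []).append(float(p))
    sids = sorted(pooled)
    actual = [hy[s] for s in sids]
    predicted = [float(np.mean(pooled[s])) for s in sids]
    return severity_report(actual, predicted, sids, alpha=config.alpha)


# ---------------------------------------------------------------------------
# full run + artifact export
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineResult:
    stage1: Stage1Result
    xai: XAIResult
    severity: SeverityReport
    config: RunConfig


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    signals, table, _ = simulate(config)
    stage1 = run_stage1(config, signals, table)
    xai = run_xai(config, stage1, signals, table)
    sev = run_stage2(config, stage1, table)
    result = PipelineResult(stage1=stage1, xai=xai, severity=sev, config=config)
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.stage1.summary.to_csv(out / "stage1_summary.csv", index=False)
    result.stage1.wilcoxon.to_csv(out / "stage1_model_comparison.csv", index=False)
    per_repeat = pd.DataFrame(
        [
            {
                "arch": e.arch, "split_seed": e.split_seed,
                "auc": e.window_metrics.auc, "accuracy": e.window_metrics.accuracy,
                "sensitivity": e.window_metrics.sensitivity,
                "specificity": e.window_metrics.specificity,
                "subject_auc": e.subject_metrics.auc,
            }
            for e in result.stage1.experiments
        ]
    )
    per_repeat.to_csv(out / "stage1_per_repeat.csv", index=False)
    for plan in result.stage1.plans:
        (out / f"split_seed{plan.seed}.json").write_text(plan.to_json())
    result.xai.stability.to_csv(out / "stability_scores.csv", index=False)
    result.xai.biomarkers.to_csv(out / "biomarker_validation.csv", index=False)
    result.severity.subjects.to_csv(out / "severity_per_subject.csv", index=False)
    report = {
        "version": result.stage1.version,
        "config_hash": result.stage1.config_hash,
        "base_seed": result.config.base_seed,
        "split_seeds": [p.seed for p in result.stage1.plans],
        "severity": {
            k: v for k, v in result.severity.to_dict().items() if k != "subjects"
        },
        "consensus_features": result.xai.consensus,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
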