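"""Synthetic VGRF gait cohort with known ground-truth effect structure.

Each subject walks with a quasi-periodic stride: every plantar sensor
carries one or two raised-Gaussian pressure bumps per gait cycle, the two
feet are anti-phased by half a period, and the two total-force channels are
the sums of their respective eight sensors.  Disease severity (Hoehn & Yahr
stage h) acts on gait *variability*, not on mean load:

* the oscillatory (dynamic) part of every channel and the cycle-to-cycle
  amplitude noise are both scaled by ``v = 1 - beta * h``
  (``variability_suppression`` beta), while a static baseline offset is
  raised so that the cycle-mean force stays constant — the "rigid, flattened"
  gait of Parkinson's disease lowers standard-deviation features while
  leaving mean-force features essentially untouched;
* the stride period is lengthened by ``1 + gamma * h`` (``speed_slowing``).

Controls have h = 0 and are untouched.  With beta = gamma = 0 the two
groups are statistically exchangeable, which is the null-calibration case.

All randomness flows from one seed; each subject draws from a substream
keyed by a stable hash of its subject id, so generation is reproducible
regardless of the order subjects are produced in.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import pandas as pd

from .io import GaitSignal, validate_subject_table


class ConfigurationError(ValueError):
    """An infeasible CohortConfig."""


# per-foot sensor templates: (base amplitude A_c in Newtons,
# [(bump center phase, bump width), ...]) — centers within the stance
# portion of the cycle, heel-strike bumps early, toe-off bumps late.
DEFAULT_SENSOR_TEMPLATES: tuple[tuple[float, tuple[tuple[float, float], ...]], ...] = (
    (380.0, ((0.12, 0.07),)),
    (300.0, ((0.18, 0.08),)),
    (260.0, ((0.25, 0.09),)),
    (220.0, ((0.33, 0.09),)),
    (240.0, ((0.40, 0.09),)),
    (280.0, ((0.15, 0.07), (0.45, 0.08))),
    (320.0, ((0.48, 0.08),)),
    (360.0, ((0.52, 0.07),)),
)

DEFAULT_HY_DISTRIBUTION: tuple[tuple[float, float], ...] = (
    (1.0, 0.08),
    (1.5, 0.12),
    (2.0, 0.25),
    (2.5, 0.30),
    (3.0, 0.25),
)  # mean 2.26, sd 0.61 — matches the cohort's reported 2.3 +/- 0.6


@dataclasses.dataclass
class CohortConfig:
    """Generator settings; defaults emulate the study cohort (93 PD, 73 CO)."""

    n_control: int = 73
    n_pd: int = 93
    hy_distribution: tuple[tuple[float, float], ...] = DEFAULT_HY_DISTRIBUTION
    record_seconds: float = 120.0
    sampling_rate_hz: float = 100.0
    stride_period_s: float = 1.1
    sensor_templates: tuple = DEFAULT_SENSOR_TEMPLATES
    amp_cv_control: float = 0.08
    variability_suppression: float = 0.3   # beta: per-unit-H&Y CV reduction
    speed_slowing: float = 0.1             # gamma: per-unit-H&Y period lengthening
    noise_sd: float = 3.0                  # additive sensor noise, Newtons
    subject_scale_sd: float = 0.0          # between-subject body-load spread
    subject_period_sd: float = 0.0         # between-subject stride-period spread
    cycle_period_jitter: float = 0.02      # within-subject per-cycle timing jitter
    seed: int = 0

    def validate(self) -> None:
        probs = np.array([p for _, p in self.hy_distribution])
        stages = np.array([s for s, _ in self.hy_distribution])
        if not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("hy_distribution probabilities must sum to 1")
        if (probs < 0).any() or (stages <= 0).any():
            raise ConfigurationError("hy_distribution stages must be > 0, probs >= 0")
        if min(self.record_seconds, self.sampling_rate_hz, self.stride_period_s) <= 0:
            raise ConfigurationError("durations and rates must be positive")
        if self.n_control < 0 or self.n_pd < 0:
            raise ConfigurationError("group sizes must be non-negative")
        if not 0 <= self.variability_suppression < 1:
            raise ConfigurationError("variability_suppression must be in [0, 1)")
        if self.speed_slowing < 0:
            raise ConfigurationError("speed_slowing must be >= 0")
        h_max = stages.max()
        if self.amp_cv_control * (1 - self.variability_suppression * h_max) < 0:
            raise ConfigurationError(
                "amp_cv_control * (1 - beta * h_max) must stay non-negative"
            )


@dataclasses.dataclass
class SubjectTruth:
    """Ground-truth generative parameters of one synthetic subject."""

    subject_id: str
    group: str                 # CO or PD
    hy_stage: float
    stride_period_s: float     # realized subject stride period
    amplitude_cv: float        # realized cycle-to-cycle amplitude CV
    scale: float               # body-load multiplier


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Substream keyed by a stable hash of the subject id."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _sample_hy(rng: np.random.Generator, distribution) -> float:
    stages = np.array([s for s, _ in distribution])
    probs = np.array([p for _, p in distribution])
    return float(rng.choice(stages, p=probs / probs.sum()))


def make_subject_truth(subject_id: str, group: str, config: CohortConfig) -> SubjectTruth:
    rng = _subject_rng(config.seed, subject_id)
    h = _sample_hy(rng, config.hy_distribution) if group == "PD" else 0.0
    v = 1.0 - config.variability_suppression * h
    period = (
        config.stride_period_s
        * (1.0 + config.speed_slowing * h)
        * (1.0 + config.subject_period_sd * rng.standard_normal())
    )
    scale = 1.0 + config.subject_scale_sd * rng.standard_normal()
    return SubjectTruth(
        subject_id=subject_id,
        group=group,
        hy_stage=h,
        stride_period_s=float(max(period, 0.5 * config.stride_period_s)),
        amplitude_cv=config.amp_cv_control * v,
        scale=float(max(scale, 0.5)),
    )


def _foot_channels(
    truth: SubjectTruth,
    config: CohortConfig,
    t: np.ndarray,
    rng: np.random.Generator,
    phase_offset: float,
) -> np.ndarray:
    """8 sensor channels for one foot (noise-free), shape T x 8."""
    v = 1.0 - config.variability_suppression * truth.hy_stage
    # per-cycle periods with timing jitter; enough cycles to cover the record
    n_cycles = int(np.ceil(t[-1] / (truth.stride_period_s * 0.8))) + 3
    periods = truth.stride_period_s * (
        1.0 + config.cycle_period_jitter * rng.standard_normal(n_cycles)
    )
    periods = np.maximum(periods, 0.25 * truth.stride_period_s)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    # shift the clock so this foot strikes phase_offset of a period later
    shifted = t + phase_offset * truth.stride_period_s
    idx = np.searchsorted(starts, shifted, side="right") - 1
    idx = np.clip(idx, 0, n_cycles - 1)
    phase = (shifted - starts[idx]) / periods[idx]
    # cycle-to-cycle amplitude noise, scaled by the severity factor v
    eps = config.amp_cv_control * v * rng.standard_normal((n_cycles, 8))
    out = np.empty((t.size, 8))
    for c, (amp, bumps) in enumerate(config.sensor_templates):
        g = np.zeros_like(phase)
        g_mean = 0.0
        for center, width in bumps:
            g += np.exp(-0.5 * ((phase - center) / width) ** 2)
            g_mean += width * np.sqrt(2.0 * np.pi)  # integral of the bump over phase
        dynamic = truth.scale * amp * v * (1.0 + eps[idx, c]) * g
        baseline = truth.scale * amp * (1.0 - v) * g_mean  # keeps cycle-mean load
        out[:, c] = dynamic + baseline
    return out


def generate_subject_signal(truth: SubjectTruth, config: CohortConfig) -> GaitSignal:
    """Synthesize one subject's 18-channel VGRF record.

    Channels 16 and 17 (left/right total force) equal the sums of their
    eight sensors before the additive sensor noise is injected.
    """
    config.validate()
    rng = _subject_rng(config.seed, truth.subject_id + "/signal")
    n = int(round(config.record_seconds * config.sampling_rate_hz))
    t = np.arange(n) / config.sampling_rate_hz
    left = _foot_channels(truth, config, t, rng, phase_offset=0.0)
    right = _foot_channels(truth, config, t, rng, phase_offset=0.5)
    channels = np.column_stack([left, right, left.sum(axis=1), right.sum(axis=1)])
    if config.noise_sd > 0:
        channels = channels + config.noise_sd * rng.standard_normal(channels.shape)
    return GaitSignal(
        subject_id=truth.subject_id,
        sampling_rate_hz=config.sampling_rate_hz,
        time_s=t,
        channels=channels,
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[GaitSignal], pd.DataFrame, list[SubjectTruth]]:
    """Generate the full cohort: signals, demographics table, ground truth.

    Deterministic given (config, seed).  Optional clinical covariates
    (updrs, tug_s, speed_m_s) are noisy correlates of the H&Y stage.
    """
    config.validate()
    width_co = max(2, len(str(config.n_control)))
    width_pd = max(2, len(str(config.n_pd)))
    ids = [(f"CO{i + 1:0{width_co}d}", "CO") for i in range(config.n_control)]
    ids += [(f"PD{i + 1:0{width_pd}d}", "PD") for i in range(config.n_pd)]
    signals, truths, rows = [], [], []
    for sid, group in ids:
        truth = make_subject_truth(sid, group, config)
        truths.append(truth)
        signals.append(generate_subject_signal(truth, config))
        crng = _subject_rng(config.seed, sid + "/clinical")
        h = truth.hy_stage
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "hy_stage": h,
                "updrs": max(0.0, 10.0 * h + 3.0 * crng.standard_normal())
                if group == "PD"
                else 0.0,
                "tug_s": max(4.0, 8.0 + 2.2 * h + 1.0 * crng.standard_normal()),
                "speed_m_s": max(0.3, 1.25 - 0.17 * h + 0.05 * crng.standard_normal()),
            }
        )
    table = validate_subject_table(pd.DataFrame(rows))
    return signals, table, truths


def truth_table(truths: list[SubjectTruth]) -> pd.DataFrame:
    """Ground-truth parameters as a flat frame (for audit files and tests)."""
    return pd.DataFrame([dataclasses.asdict(tr) for tr in truths])
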