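"""Fixed-length overlapping windows and the 18-token x 2-feature representation.

Each record is cut into windows of ``window_len`` samples (default 100, i.e.
1 s at 100 Hz) with 50% overlap; for every window and channel the mean and
standard deviation are computed, yielding 18 tokens (16 sensors + two total
forces) with 2 feature dimensions each.  Model inputs are z-scored with
per-channel statistics fitted on *training subjects only* — the fitted stats
remember which subjects contributed so downstream code can assert that no
validation/test subject leaked into normalization.  The same window
summaries on the raw, unnormalized signal (``raw_features``) feed the
biomarker statistics, which must stay in physical force units.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import CHANNEL_NAMES, N_CHANNELS, GaitSignal

#: canonical 36 flat feature names, token-major: sensor_1_mean, sensor_1_std, ...
FEATURE_NAMES: list[str] = [
    f"{ch}_{stat}" for ch in CHANNEL_NAMES for stat in ("mean", "std")
]


class RecordTooShort(ValueError):
    """Record has fewer samples than one window; distinctly reportable."""


@dataclasses.dataclass
class WindowConfig:
    window_len: int = 100
    overlap: float = 0.5
    epsilon: float = 1e-8  # std floor below which a channel counts as constant

    def __post_init__(self):
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def step(self) -> int:
        """Hop between window starts: L*(1-overlap) rounded to nearest, >= 1."""
        return max(1, int(np.floor(self.window_len * (1.0 - self.overlap) + 0.5)))


def segment(signal: GaitSignal, config: WindowConfig) -> list[tuple[int, int]]:
    """Window start/stop index ranges; trailing partial window discarded."""
    T, L = signal.n_samples, config.window_len
    if T < L:
        raise RecordTooShort(
            f"record {signal.subject_id!r} has {T} samples < window_len {L}"
        )
    step = config.step
    n = (T - L) // step + 1
    return [(i * step, i * step + L) for i in range(n)]


@dataclasses.dataclass
class ChannelStats:
    """Per-channel z-score statistics, tagged with the subjects they came from."""

    mean: np.ndarray           # (18,)
    std: np.ndarray            # (18,), floored: values < epsilon replaced by 1
    subject_ids: frozenset[str]

    def normalize(self, channels: np.ndarray) -> np.ndarray:
        return (channels - self.mean) / self.std


def fit_channel_stats(signals: list[GaitSignal], epsilon: float = 1e-8) -> ChannelStats:
    """Per-channel mean/std over all samples of the given (training) signals."""
    if not signals:
        raise ValueError("cannot fit channel stats on an empty training set")
    stacked = np.concatenate([s.channels for s in signals], axis=0)
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0)
    std = np.where(std < epsilon, 1.0, std)
    return ChannelStats(
        mean=mean, std=std, subject_ids=frozenset(s.subject_id for s in signals)
    )


def assert_stats_clean(stats: ChannelStats, training_subjects: set[str]) -> None:
    """Fail if any non-training subject contributed samples to the stats."""
    leaked = stats.subject_ids - set(training_subjects)
    if leaked:
        raise AssertionError(
            f"normalization statistics contaminated by non-training subjects: "
            f"{sorted(leaked)}"
        )


@dataclasses.dataclass
class TokenizedWindow:
    subject_id: str
    label: int                  # 0 = CO, 1 = PD
    features: np.ndarray        # (18, 2): normalized per-channel (mean, std)
    raw_features: np.ndarray    # (18, 2): same summaries on the raw signal

    def __post_init__(self):
        for arr in (self.features, self.raw_features):
            if arr.shape != (N_CHANNELS, 2):
                raise ValueError(f"features must be {N_CHANNELS} x 2, got {arr.shape}")


def tokenize(
    signal: GaitSignal,
    windows: list[tuple[int, int]],
    stats: ChannelStats,
    subject_id: str,
    label: int,
) -> list[TokenizedWindow]:
    """One TokenizedWindow per index range.

    Normalized mean of a window is algebraically (raw_mean - mu_c) / sigma_c
    and normalized std is raw_std / sigma_c; both are computed directly on
    the z-scored samples.
    """
    normalized = stats.normalize(signal.channels)
    out = []
    for start, stop in windows:
        raw = signal.channels[start:stop]
        norm = normalized[start:stop]
        out.append(
            TokenizedWindow(
                subject_id=subject_id,
                label=int(label),
                features=np.stack([norm.mean(axis=0), norm.std(axis=0)], axis=1),
                raw_features=np.stack([raw.mean(axis=0), raw.std(axis=0)], axis=1),
            )
        )
    return out


def windows_to_frame(windows: list[TokenizedWindow], raw: bool = False) -> pd.DataFrame:
    """Flat export: subject_id, label + the 36 canonical feature columns."""
    feats = np.array(
        [(w.raw_features if raw else w.features).reshape(-1) for w in windows]
    )
    frame = pd.DataFrame(feats, columns=FEATURE_NAMES)
    frame.insert(0, "label", [w.label for w in windows])
    frame.insert(0, "subject_id", [w.subject_id for w in windows])
    return frame


def feature_matrix(windows: list[TokenizedWindow]) -> np.ndarray:
    """Model-input array of shape (n_windows, 18, 2)."""
    return np.stack([w.features for w in windows]) if windows else np.empty((0, 18, 2))


def labels_of(windows: list[TokenizedWindow]) -> np.ndarray:
    return np.array([w.label for w in windows], dtype=int)
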