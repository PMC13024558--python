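"""Reading and writing VGRF gait records and the cohort demographics table.

The on-disk record dialect follows the PhysioNet gait database for
Parkinson's disease: plain whitespace-delimited text, one sample per line,
19 columns — time in seconds followed by 18 force channels in Newtons
(8 left plantar sensors, 8 right plantar sensors, left total force, right
total force).  Lines starting with '#' are treated as comments.

This module is the single I/O boundary; the synthetic cohort generator and
any real download both pass through it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

N_CHANNELS = 18
#: canonical flat channel names, in on-disk column order
CHANNEL_NAMES = (
    [f"sensor_{i}" for i in range(1, 9)]       # left foot sensors 1-8
    + [f"sensor_{i}" for i in range(9, 17)]    # right foot sensors 9-16
    + ["total_l", "total_r"]
)


class FormatError(ValueError):
    """A VGRF file violates the 19-column whitespace dialect."""


class ValidationError(ValueError):
    """A demographics table violates its invariants."""


@dataclasses.dataclass
class GaitSignal:
    """One subject's multichannel VGRF record.

    channels is a T x 18 float array: columns 0-7 left sensors, 8-15 right
    sensors, 16 left total force, 17 right total force (Newtons).
    """

    subject_id: str
    sampling_rate_hz: float
    time_s: np.ndarray
    channels: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.channels.ndim != 2 or self.channels.shape[1] != N_CHANNELS:
            raise ValidationError(
                f"channels must be T x {N_CHANNELS}, got {self.channels.shape}"
            )
        if self.channels.shape[0] < 1:
            raise ValidationError("record must contain at least one sample (T >= 1)")
        if self.time_s.shape != (self.channels.shape[0],):
            raise ValidationError("time_s length must match channel rows")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError("time must be strictly increasing")
        if not (np.isfinite(self.time_s).all() and np.isfinite(self.channels).all()):
            raise ValidationError("non-finite values in record")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]


def read_vgrf_file(path, subject_id: str, sampling_rate_hz: float = 100.0) -> GaitSignal:
    """Parse a 19-column whitespace-delimited VGRF text file.

    Raises FormatError naming the offending line on a wrong column count or
    a non-numeric token.  '#'-prefixed lines are ignored.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != N_CHANNELS + 1:
                raise FormatError(
                    f"{path}: line {lineno}: expected {N_CHANNELS + 1} columns, "
                    f"got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric token") from exc
    if not rows:
        raise FormatError(f"{path}: no data lines")
    arr = np.asarray(rows, dtype=float)
    return GaitSignal(
        subject_id=subject_id,
        sampling_rate_hz=sampling_rate_hz,
        time_s=arr[:, 0],
        channels=arr[:, 1:],
    )


def write_vgrf_file(signal: GaitSignal, path) -> None:
    """Write a GaitSignal in the 19-column dialect, 6 significant digits."""
    mat = np.column_stack([signal.time_s, signal.channels])
    with open(path, "w") as fh:
        fh.write(f"# subject={signal.subject_id} fs_hz={signal.sampling_rate_hz:g}\n")
        for row in mat:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


REQUIRED_DEMOGRAPHIC_COLS = ("subject_id", "group", "hy_stage")


def validate_subject_table(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce the demographics invariants; returns the validated frame.

    subject_id unique; group in {CO, PD}; CO implies hy_stage == 0 and PD
    implies hy_stage > 0.
    """
    for col in REQUIRED_DEMOGRAPHIC_COLS:
        if col not in table.columns:
            raise ValidationError(f"demographics table missing column '{col}'")
    table = table.copy()
    table["subject_id"] = table["subject_id"].astype(str)
    if table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id(s): {dups}")
    bad_group = set(table["group"]) - {"CO", "PD"}
    if bad_group:
        raise ValidationError(f"unknown group label(s): {sorted(bad_group)}")
    table["hy_stage"] = table["hy_stage"].astype(float)
    if (table["hy_stage"] < 0).any():
        raise ValidationError("hy_stage must be >= 0")
    co_bad = table[(table["group"] == "CO") & (table["hy_stage"] > 0)]
    if len(co_bad):
        raise ValidationError(
            f"CO subjects with hy_stage > 0: {co_bad['subject_id'].tolist()}"
        )
    pd_bad = table[(table["group"] == "PD") & (table["hy_stage"] <= 0)]
    if len(pd_bad):
        raise ValidationError(
            f"PD subjects with hy_stage <= 0: {pd_bad['subject_id'].tolist()}"
        )
    return table.reset_index(drop=True)


def read_demographics(path) -> pd.DataFrame:
    """Load and validate the demographics CSV (subject_id, group, hy_stage, ...)."""
    return validate_subject_table(pd.read_csv(path))


def write_demographics(table: pd.DataFrame, path) -> None:
    validate_subject_table(table).to_csv(path, index=False)
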