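"""Repeated subject-wise 70/15/15 partitioning with hard leakage guards.

The unit of segregation is the subject: every window of a subject lives in
exactly one of train/validation/test.  Splits are stratified by group so
both classes appear in every partition (AUC needs both), subject counts per
partition follow largest-remainder rounding of the ratios within each
class, and each repeat uses seed ``base_seed + k``.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

PARTITIONS = ("train", "val", "test")


class SplitError(ValueError):
    """The requested partitioning is infeasible."""


class LeakageError(AssertionError):
    """A subject's windows appear in more than one partition."""


@dataclasses.dataclass
class SplitPlan:
    seed: int
    assignment: dict[str, str]  # subject_id -> train/val/test

    def subjects(self, partition: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == partition]

    @property
    def realized_fractions(self) -> dict[str, float]:
        n = len(self.assignment)
        return {p: len(self.subjects(p)) / n for p in PARTITIONS}

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "assignment": self.assignment}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        obj = json.loads(text)
        return cls(seed=obj["seed"], assignment=obj["assignment"])


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Apportion n seats to ratios; ties broken by partition order."""
    quotas = [n * r for r in ratios]
    base = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def make_split(
    subject_table: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> SplitPlan:
    """One stratified subject-wise split, deterministic per seed."""
    if len(ratios) != 3 or not np.isclose(sum(ratios), 1.0):
        raise SplitError("ratios must be three numbers summing to 1")
    assignment: dict[str, str] = {}
    rng = np.random.default_rng(seed)
    for group in ("CO", "PD"):
        ids = sorted(subject_table.loc[subject_table["group"] == group, "subject_id"])
        if len(ids) < 3:
            raise SplitError(f"need >= 3 subjects in class {group}, got {len(ids)}")
        counts = _largest_remainder(len(ids), tuple(ratios))
        shuffled = list(rng.permutation(ids))
        pos = 0
        for partition, k in zip(PARTITIONS, counts):
            for sid in shuffled[pos : pos + k]:
                assignment[sid] = partition
            pos += k
    for partition in PARTITIONS:
        present = {
            subject_table.set_index("subject_id")["group"][s]
            for s, p in assignment.items()
            if p == partition
        }
        if present != {"CO", "PD"}:
            raise SplitError(
                f"partition {partition!r} lacks a class (has {sorted(present)}); "
                "too few subjects for these ratios"
            )
    return SplitPlan(seed=seed, assignment=assignment)


def make_repeated_splits(
    subject_table: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15),
    n_repeats: int = 5,
    base_seed: int = 0,
) -> list[SplitPlan]:
    if n_repeats < 1:
        raise SplitError("n_repeats must be >= 1")
    return [
        make_split(subject_table, ratios, seed=base_seed + k) for k in range(n_repeats)
    ]


@dataclasses.dataclass
class LeakageReport:
    ok: bool
    offenders: list[str]


def assert_no_leakage(
    window_subjects: list[str],
    window_partitions: list[str],
    strict: bool = False,
) -> LeakageReport:
    """Check that no subject's windows occur in two or more partitions.

    Takes the realized window-level partition labels (however they were
    produced — a SplitPlan gives clean ones by construction; a record-wise
    split will not).  With strict=True a violation raises LeakageError
    naming the offending subjects.
    """
    seen: dict[str, set[str]] = {}
    for sid, part in zip(window_subjects, window_partitions, strict=True):
        seen.setdefault(sid, set()).add(part)
    offenders = sorted(s for s, parts in seen.items() if len(parts) > 1)
    report = LeakageReport(ok=not offenders, offenders=offenders)
    if strict and offenders:
        raise LeakageError(f"subject-level leakage: {offenders}")
    return report
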