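"""Stability-consensus feature selection across models and splits.

In every (architecture x split) experiment the features whose aggregate
Integrated-Gradients contribution lies within the top fraction (default
20%, k = ceil(0.2 * 36) = 8 of the 36 token features) are marked important.
A feature's stability score is the fraction of experiments that marked it;
features scoring at or above the consensus threshold (default 20%,
inclusive) form the consensus biomarker candidate set.  With 5 splits and
3 architectures there are 15 experiments; the count is configurable.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .attribution import AttributionRecord
from .windowing import FEATURE_NAMES

DEFAULT_TOP_FRACTION = 0.2
DEFAULT_CONSENSUS_THRESHOLD = 0.2


def top_fraction_features(
    record: AttributionRecord, fraction: float = DEFAULT_TOP_FRACTION
) -> list[str]:
    """The k = ceil(fraction * n) features with largest aggregate attribution.

    Ties at the cut are broken by canonical feature order (the fixed
    FEATURE_NAMES sequence), so selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    names = list(record.feature_names)
    if not names:
        raise ValueError("empty attribution record")
    k = math.ceil(fraction * len(names))
    order = sorted(range(len(names)), key=lambda i: (-record.values[i], i))
    return [names[i] for i in order[:k]]


def stability_scores(
    subsets: list[list[str]], feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature selection count and score = count / n_experiments."""
    if not subsets:
        raise ValueError("need at least one experiment subset")
    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    n_exp = len(subsets)
    counts = {f: 0 for f in names}
    for subset in subsets:
        for f in subset:
            counts[f] += 1
    return pd.DataFrame(
        {
            "feature": names,
            "count": [counts[f] for f in names],
            "n_experiments": n_exp,
            "score": [counts[f] / n_exp for f in names],
        }
    )


def consensus_features(
    table: pd.DataFrame, threshold: float = DEFAULT_CONSENSUS_THRESHOLD
) -> list[str]:
    """Features with score >= threshold ('20% or more' is inclusive),
    ordered by score descending then canonical name order."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    canon = {f: i for i, f in enumerate(table["feature"])}
    hits = table[table["score"] >= threshold]
    ordered = sorted(
        hits["feature"], key=lambda f: (-float(hits.set_index("feature")["score"][f]), canon[f])
    )
    return ordered


def stability_table(
    records: list[AttributionRecord],
    fraction: float = DEFAULT_TOP_FRACTION,
    threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
) -> pd.DataFrame:
    """End-to-end: top-fraction subsets -> scores -> consensus flag column."""
    subsets = [top_fraction_features(r, fraction) for r in records]
    names = list(records[0].feature_names)
    table = stability_scores(subsets, feature_names=names)
    table["consensus"] = table["score"] >= threshold
    return table
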