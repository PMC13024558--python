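import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitpd.stats import (
    bh_fdr,
    cliffs_delta,
    mann_whitney_u,
    summarize_feature,
    validate_features,
)


def bruteforce_u_and_delta(x, y):
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    eq = sum(1 for a in x for b in y if a == b)
    u = gt + 0.5 * eq
    delta = (gt - lt) / (len(x) * len(y))
    return u, delta


def hand_bh(p):
    """Step-up: adjusted_(i) = min_{j>=i} p_(j) * m / j, clipped to 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = min(1.0, running)
    return adjusted


def test_exact_small_sample_example():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(2 / 6)


def test_identical_samples_p_near_one():
    _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0, abs=1e-9)


def test_exact_and_asymptotic_branches_agree():
    rng = np.random.default_rng(0)
    for _ in range(10):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        _, p_exact = mann_whitney_u(x, y)
        from scipy.stats import mannwhitneyu

        p_approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p_exact == pytest.approx(p_approx, abs=0.02)


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])
    with pytest.raises(ValueError):
        cliffs_delta([1.0], [])


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [4, 5, 6], -1.0),
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 3], [2, 4], -0.5),
    ],
)
def test_cliffs_delta_examples(x, y, expected):
    assert cliffs_delta(x, y) == pytest.approx(expected)


@settings(max_examples=200, deadline=None)
@given(
    nx=st.integers(1, 25),
    ny=st.integers(1, 25),
    seed=st.integers(0, 10_000),
)
def test_u_and_delta_match_pair_enumeration(nx, ny, seed):
    rng = np.random.default_rng(seed)
    x = rng.choice(np.linspace(0, 1, 9), nx)  # discrete values force ties
    y = rng.choice(np.linspace(0, 1, 9), ny)
    u_ref, delta_ref = bruteforce_u_and_delta(x, y)
    u, _ = mann_whitney_u(x, y)
    assert u == pytest.approx(u_ref)
    assert cliffs_delta(x, y) == pytest.approx(delta_ref)


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.25], [0.25]),
        ([0.001, 0.5], [0.002, 0.5]),
    ],
)
def test_bh_printed_examples(p, expected):
    np.testing.assert_allclose(bh_fdr(p), expected)


def test_bh_matches_hand_stepup_on_random_vectors():
    rng = np.random.default_rng(1)
    for _ in range(50):
        p = rng.random(rng.integers(1, 30))
        np.testing.assert_allclose(bh_fdr(p), hand_bh(p), atol=1e-12)


def test_bh_monotone_in_raw_p():
    rng = np.random.default_rng(2)
    for _ in range(30):
        p = rng.random(10)
        bumped = p.copy()
        i = rng.integers(10)
        bumped[i] = min(1.0, p[i] + rng.random() * (1 - p[i]))
        assert (bh_fdr(bumped) >= bh_fdr(p) - 1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_summarize_feature_quantiles_by_hand():
    result = summarize_feature([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], feature="f")
    assert result.control_median == 3.0
    assert result.control_iqr == 2.0  # Q3=4, Q1=2 under linear interpolation
    assert result.cliffs_delta == 0.0
    assert result.p_raw == pytest.approx(1.0, abs=0.05)
    assert result.p_adjusted >= result.p_raw


def test_validate_features_family_adjustment():
    rng = np.random.default_rng(3)
    n = 300
    frame = pd.DataFrame(
        {
            "subject_id": ["s"] * (2 * n),
            "label": [0] * n + [1] * n,
            "shifted": np.r_[rng.normal(0, 1, n), rng.normal(-1.5, 1, n)],
            "nullfeat": rng.normal(0, 1, 2 * n),
        }
    )
    out = validate_features(frame, ["shifted", "nullfeat"])
    row = out.set_index("feature")
    assert row.loc["shifted", "p_adjusted"] < 0.001
    assert row.loc["shifted", "cliffs_delta"] < -0.5  # PD below control
    assert row.loc["nullfeat", "p_adjusted"] > 0.05
    assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()
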