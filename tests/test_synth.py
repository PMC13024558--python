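import numpy as np
import pytest

from gaitpd.pipeline import tokenize_cohort_raw
from gaitpd.stats import mann_whitney_u
from gaitpd.synth import (
    CohortConfig,
    ConfigurationError,
    generate_cohort,
    generate_subject_signal,
    make_subject_truth,
)
from gaitpd.windowing import WindowConfig


def test_same_config_and_seed_is_deterministic():
    config = CohortConfig(n_control=2, n_pd=2, record_seconds=5.0, seed=11)
    sig_a, table_a, _ = generate_cohort(config)
    sig_b, table_b, _ = generate_cohort(config)
    for a, b in zip(sig_a, sig_b):
        np.testing.assert_array_equal(a.channels, b.channels)
    assert table_a.equals(table_b)


def test_totals_are_sensor_sums_before_noise():
    config = CohortConfig(n_control=1, n_pd=1, record_seconds=5.0, noise_sd=0.0, seed=1)
    signals, _, _ = generate_cohort(config)
    for sig in signals:
        np.testing.assert_allclose(sig.channels[:, 16], sig.channels[:, :8].sum(axis=1))
        np.testing.assert_allclose(sig.channels[:, 17], sig.channels[:, 8:16].sum(axis=1))


def test_zero_noise_zero_cv_gives_identical_cycles():
    config = CohortConfig(
        n_control=1, n_pd=0, record_seconds=6.0, stride_period_s=1.0,
        amp_cv_control=0.0, noise_sd=0.0, cycle_period_jitter=0.0, seed=2,
    )
    truth = make_subject_truth("CO01", "CO", config)
    sig = generate_subject_signal(truth, config)
    period = 100  # 1.0 s at 100 Hz, exact sample alignment
    np.testing.assert_allclose(
        sig.channels[:-period], sig.channels[period:], atol=1e-9
    )


def test_realized_amplitude_cv_decreases_monotonically_in_severity():
    config = CohortConfig(variability_suppression=0.3, seed=0)
    cvs = [
        config.amp_cv_control * (1 - config.variability_suppression * h)
        for h in (0, 1, 1.5, 2, 2.5, 3)
    ]
    assert all(a > b for a, b in zip(cvs, cvs[1:]))
    # and the generator reports exactly this value as its ground truth
    truth = make_subject_truth("PD01", "PD", config)
    expected = config.amp_cv_control * (1 - config.variability_suppression * truth.hy_stage)
    assert truth.amplitude_cv == pytest.approx(expected)


def test_severity_lowers_std_features_not_mean_features():
    """The planted effect: window std falls with H&Y while window mean holds."""
    base = dict(n_control=1, n_pd=0, record_seconds=20.0, noise_sd=0.0, seed=5)
    config = CohortConfig(**base)
    truth_lo = make_subject_truth("X1", "CO", config)
    truth_hi = make_subject_truth("X1", "CO", config)
    truth_hi.hy_stage = 3.0  # same subject stream, forced severity
    sig_lo = generate_subject_signal(truth_lo, config)
    sig_hi = generate_subject_signal(truth_hi, config)
    std_lo = sig_lo.channels[:, 0].std()
    std_hi = sig_hi.channels[:, 0].std()
    assert std_hi < 0.5 * std_lo
    mean_lo = sig_lo.channels[:, 0].mean()
    mean_hi = sig_hi.channels[:, 0].mean()
    assert mean_hi == pytest.approx(mean_lo, rel=0.05)


def test_null_config_groups_are_exchangeable():
    """beta = gamma = 0: a two-sample test on a token feature is
    non-significant at alpha = 0.05 in >= 90% of 20 seeds."""
    non_significant = 0
    for seed in range(20):
        config = CohortConfig(
            n_control=8, n_pd=8, record_seconds=10.0,
            variability_suppression=0.0, speed_slowing=0.0, seed=300 + seed,
        )
        signals, table, _ = generate_cohort(config)
        raw = tokenize_cohort_raw(signals, table, WindowConfig())
        x = raw.loc[raw["label"] == 1, "sensor_1_std"].to_numpy()
        y = raw.loc[raw["label"] == 0, "sensor_1_std"].to_numpy()
        _, p = mann_whitney_u(x, y)
        non_significant += p >= 0.05
    assert non_significant >= 18


def test_pd_stage_distribution_matches_cohort_profile():
    config = CohortConfig(seed=9)
    stages = [
        make_subject_truth(f"PD{i:03d}", "PD", config).hy_stage for i in range(300)
    ]
    assert np.mean(stages) == pytest.approx(2.26, abs=0.15)
    assert np.std(stages) == pytest.approx(0.61, abs=0.15)
    assert set(stages) <= {1.0, 1.5, 2.0, 2.5, 3.0}


@pytest.mark.parametrize(
    "kwargs",
    [
        {"hy_distribution": ((1.0, 0.5), (2.0, 0.4))},          # probs don't sum to 1
        {"record_seconds": 0.0},
        {"variability_suppression": 1.5},
        {"amp_cv_control": 0.5, "variability_suppression": 0.5},  # CV negative at h=3
    ],
)
def test_infeasible_configs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        CohortConfig(**kwargs).validate()
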