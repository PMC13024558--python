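import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitpd.severity import (
    SUBJECT_FEATURE_NAMES,
    SeverityModelConfig,
    effect_size_f2,
    posthoc_power,
    regression_metrics,
    severity_report,
    subject_features,
    train_severity_model,
)
from gaitpd.windowing import TokenizedWindow

# the worked example: ten (actual, predicted) continuous H&Y pairs whose
# published summary metrics pin down the metric implementations end to end
WORKED_ACTUAL = [0, 3, 2, 0, 2, 2, 2, 3, 2, 0]
WORKED_PREDICTED = [-0.055, 3.093, 1.887, -0.037, 2.024, 2.158, 2.130, 2.365, 1.669, 0.006]


def window(features, subject="s", label=1):
    arr = np.asarray(features, dtype=float).reshape(18, 2)
    return TokenizedWindow(subject, label, arr.copy(), arr.copy())


def test_identical_windows_have_zero_across_window_std():
    w = window(np.arange(36))
    vec = subject_features([w, w, w])
    assert vec.shape == (72,)
    np.testing.assert_allclose(vec[1::2], 0.0)  # every *_wstd entry
    np.testing.assert_allclose(vec[0::2], np.arange(36))


def test_single_window_means_are_that_window():
    vec = subject_features([window(np.arange(36))])
    np.testing.assert_allclose(vec[0::2], np.arange(36))
    np.testing.assert_allclose(vec[1::2], 0.0)


def test_permutation_invariance():
    rng = np.random.default_rng(0)
    ws = [window(rng.normal(size=36)) for _ in range(6)]
    np.testing.assert_allclose(subject_features(ws), subject_features(ws[::-1]))


def test_no_windows_rejected():
    with pytest.raises(ValueError):
        subject_features([])


def make_frame(n, seed=0, noise=0.0):
    """Subject frames with hy_stage a monotone function of one feature."""
    rng = np.random.default_rng(seed)
    h = rng.choice([0.0, 1.0, 2.0, 3.0], size=n)
    data = {"subject_id": [f"s{i}" for i in range(n)], "hy_stage": h}
    for j, name in enumerate(SUBJECT_FEATURE_NAMES):
        if j == 0:
            data[name] = 10.0 - 2.0 * h + noise * rng.standard_normal(n)
        else:
            data[name] = rng.standard_normal(n)
    return pd.DataFrame(data)


def test_constant_target_predicts_constant():
    frame = make_frame(30, seed=1)
    frame["hy_stage"] = 2.0
    model = train_severity_model(frame, SeverityModelConfig(seed=0))
    preds = model.predict(frame[SUBJECT_FEATURE_NAMES])
    np.testing.assert_allclose(preds, 2.0, atol=1e-3)


def test_same_seed_identical_predictions():
    frame = make_frame(40, seed=2)
    test = make_frame(10, seed=3)
    a = train_severity_model(frame, SeverityModelConfig(seed=5)).predict(test[SUBJECT_FEATURE_NAMES])
    b = train_severity_model(frame, SeverityModelConfig(seed=5)).predict(test[SUBJECT_FEATURE_NAMES])
    np.testing.assert_array_equal(a, b)


def test_noiseless_monotone_target_recovered():
    from scipy.stats import spearmanr

    train = make_frame(60, seed=4)
    test = make_frame(25, seed=5)
    model = train_severity_model(train, SeverityModelConfig(seed=0))
    preds = model.predict(test[SUBJECT_FEATURE_NAMES])
    rho, _ = spearmanr(test["hy_stage"], preds)
    assert rho >= 0.9


def test_train_test_overlap_aborts():
    frame = make_frame(20, seed=6)
    with pytest.raises(AssertionError, match="overlap"):
        train_severity_model(frame, test_subjects={"s3", "zzz"})


def test_worked_example_reproduces_published_metrics():
    m = regression_metrics(WORKED_ACTUAL, WORKED_PREDICTED)
    assert round(m["mae"], 3) == 0.158
    assert round(m["rmse"], 3) == 0.241
    assert round(m["r2"], 3) == 0.953
    assert round(m["spearman_rho"], 3) == 0.921


def test_perfect_and_constant_predictors():
    m = regression_metrics([1, 2, 3], [1, 2, 3])
    assert m["mae"] == 0 and m["rmse"] == 0 and m["r2"] == 1 and m["spearman_rho"] == 1
    m = regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
    assert m["r2"] == pytest.approx(0.0)


def test_zero_variance_actual_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        regression_metrics([2.0, 2.0], [1.0, 3.0])


@settings(max_examples=100, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 50))
def test_mae_never_exceeds_rmse(seed, n):
    rng = np.random.default_rng(seed)
    actual = rng.normal(size=n)
    if np.allclose(actual, actual[0]):
        return
    m = regression_metrics(actual, rng.normal(size=n))
    assert m["mae"] <= m["rmse"] + 1e-12


@pytest.mark.parametrize("r2,expected", [(0.5, 1.0), (0.0, 0.0), (0.953, 20.28)])
def test_effect_size_f2(r2, expected):
    assert effect_size_f2(r2) == pytest.approx(expected, abs=0.005)


def test_f2_undefined_at_r2_one():
    with pytest.raises(ValueError):
        effect_size_f2(1.0)


def test_power_is_alpha_at_zero_effect():
    for alpha in (0.01, 0.05, 0.2):
        assert posthoc_power(0.0, 50, 5, alpha=alpha) == pytest.approx(alpha, abs=1e-10)


def test_power_monotone_in_sample_size():
    powers = [posthoc_power(0.35, n, 5) for n in (10, 20, 40, 80, 160)]
    assert all(a < b for a, b in zip(powers, powers[1:]))


def test_power_infeasible_dfs_rejected():
    with pytest.raises(ValueError):
        posthoc_power(0.5, 5, 5)


def test_severity_report_assembles_consistent_fields():
    report = severity_report(
        WORKED_ACTUAL, WORKED_PREDICTED, [f"s{i}" for i in range(10)]
    )
    assert report.mae <= report.rmse
    assert report.f2 == pytest.approx(effect_size_f2(report.r2))
    assert 0 <= report.power <= 1
    assert len(report.subjects) == 10
    np.testing.assert_allclose(
        report.subjects["abs_difference"],
        np.abs(np.array(WORKED_ACTUAL) - np.array(WORKED_PREDICTED)),
    )
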