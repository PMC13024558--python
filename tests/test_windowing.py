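import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitpd.io import GaitSignal
from gaitpd.windowing import (
    FEATURE_NAMES,
    RecordTooShort,
    WindowConfig,
    assert_stats_clean,
    fit_channel_stats,
    segment,
    tokenize,
    windows_to_frame,
)


def make_signal(T, subject_id="S1", fill=None, seed=0):
    rng = np.random.default_rng(seed)
    channels = rng.normal(100, 20, size=(T, 18)) if fill is None else np.full((T, 18), fill)
    return GaitSignal(subject_id, 100.0, np.arange(T) / 100.0, channels)


def test_standard_config_window_count():
    windows = segment(make_signal(1000), WindowConfig(window_len=100, overlap=0.5))
    assert len(windows) == 19
    assert windows[0] == (0, 100)
    assert windows[1] == (50, 150)


def test_exact_fit_gives_single_window():
    assert segment(make_signal(100), WindowConfig(100, 0.5)) == [(0, 100)]


def test_too_short_record_reported_distinctly():
    with pytest.raises(RecordTooShort):
        segment(make_signal(99), WindowConfig(100, 0.5))


@settings(max_examples=200, deadline=None)
@given(
    T=st.integers(2, 600),
    L=st.integers(2, 200),
    overlap=st.floats(0.0, 0.95),
)
def test_window_count_matches_bruteforce_enumeration(T, L, overlap):
    """floor((T-L)/step)+1 equals enumerating every valid start position."""
    config = WindowConfig(window_len=L, overlap=overlap)
    step = config.step
    expected = [(s, s + L) for s in range(0, T - L + 1, step)] if T >= L else None
    if expected is None:
        with pytest.raises(RecordTooShort):
            segment(make_signal(T), config)
    else:
        assert segment(make_signal(T), config) == expected


def test_constant_channel_std_floored_and_normalizes_to_zero():
    sig = make_signal(200, fill=7.0)
    stats = fit_channel_stats([sig], epsilon=1e-8)
    np.testing.assert_array_equal(stats.std, np.ones(18))
    np.testing.assert_allclose(stats.normalize(sig.channels), 0.0)


def test_fitted_stats_recover_standard_normal():
    rng = np.random.default_rng(1)
    sig = GaitSignal("S", 100.0, np.arange(100_000) / 100.0, rng.standard_normal((100_000, 18)))
    stats = fit_channel_stats([sig])
    assert np.abs(stats.mean).max() < 0.02
    assert np.abs(stats.std - 1).max() < 0.02


def test_zscore_of_training_data_is_standardized():
    sig = make_signal(5000, seed=2)
    stats = fit_channel_stats([sig])
    normalized = stats.normalize(sig.channels)
    np.testing.assert_allclose(normalized.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(normalized.std(axis=0), 1.0, atol=1e-10)


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        fit_channel_stats([])


def test_tokenize_shapes_and_raw_values():
    sig = make_signal(300, fill=5.0)
    stats = fit_channel_stats([make_signal(300, seed=4)])
    windows = tokenize(sig, segment(sig, WindowConfig()), stats, "S1", 1)
    assert len(windows) == 5
    for w in windows:
        assert w.features.shape == (18, 2)
        assert w.raw_features.shape == (18, 2)
        np.testing.assert_allclose(w.raw_features[:, 0], 5.0)   # constant k -> mean k
        np.testing.assert_allclose(w.raw_features[:, 1], 0.0)   # std 0
        assert w.subject_id == "S1" and w.label == 1


def test_normalized_mean_is_affine_in_raw_mean():
    sig = make_signal(400, seed=5)
    stats = fit_channel_stats([make_signal(400, seed=6)])
    windows = tokenize(sig, segment(sig, WindowConfig()), stats, "S1", 0)
    for w in windows:
        np.testing.assert_allclose(
            w.features[:, 0], (w.raw_features[:, 0] - stats.mean) / stats.std
        )
        np.testing.assert_allclose(w.features[:, 1], w.raw_features[:, 1] / stats.std)


def test_stats_leakage_assertion():
    stats = fit_channel_stats([make_signal(200, "train_a"), make_signal(200, "test_z")])
    with pytest.raises(AssertionError, match="test_z"):
        assert_stats_clean(stats, {"train_a"})
    assert_stats_clean(stats, {"train_a", "test_z"})  # clean case passes


def test_flat_export_has_canonical_columns():
    sig = make_signal(200)
    stats = fit_channel_stats([sig])
    windows = tokenize(sig, segment(sig, WindowConfig()), stats, "S1", 0)
    frame = windows_to_frame(windows)
    assert list(frame.columns) == ["subject_id", "label"] + FEATURE_NAMES
    assert frame.shape == (len(windows), 38)
    assert "sensor_1_std" in frame.columns and "total_r_mean" in frame.columns
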