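import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from gaitpd.evaluate import (
    aggregate_repeats,
    compute_metrics,
    confusion_matrix,
    paired_wilcoxon,
    subject_level,
    window_auc,
    MetricSet,
)


def bruteforce_auc(probs, labels):
    pos = [p for p, l in zip(probs, labels) if l == 1]
    neg = [p for p, l in zip(probs, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_perfect_separation():
    m = compute_metrics([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
    assert m.auc == 1.0 and m.accuracy == 1.0
    assert m.sensitivity == 1.0 and m.specificity == 1.0


def test_three_of_four_concordant_pairs():
    assert window_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75


def test_all_tied_probabilities_give_half():
    assert window_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5


def test_one_class_labels_rejected():
    with pytest.raises(ValueError, match="both classes"):
        window_auc([0.1, 0.9], [1, 1])


@settings(max_examples=150, deadline=None)
@given(
    n=st.integers(4, 60),
    seed=st.integers(0, 10_000),
    ties=st.booleans(),
)
def test_auc_matches_bruteforce_and_sklearn(n, seed, ties):
    rng = np.random.default_rng(seed)
    probs = rng.choice(np.linspace(0, 1, 7), n) if ties else rng.random(n)
    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    labels = rng.permutation(labels)
    auc = window_auc(probs, labels)
    assert auc == pytest.approx(bruteforce_auc(probs, labels))
    assert auc == pytest.approx(roc_auc_score(labels, probs))


def test_subject_level_mean_and_invariance():
    out = subject_level([0.2, 0.4, 0.9], ["a", "a", "b"], [0, 0, 1])
    assert dict(zip(out["subject_id"], out["prob"])) == {"a": pytest.approx(0.3), "b": 0.9}
    shuffled = subject_level([0.9, 0.4, 0.2], ["b", "a", "a"], [1, 0, 0])
    assert out.equals(shuffled)


def test_subject_level_inconsistent_labels_rejected():
    with pytest.raises(ValueError, match="inconsistent"):
        subject_level([0.1, 0.9], ["a", "a"], [0, 1])


def metric_sets(values):
    return [MetricSet(v, v, v, v, 0.5, "window") for v in values]


def test_aggregate_identical_repeats():
    agg = aggregate_repeats(metric_sets([0.9] * 5))
    auc = agg.metrics["auc"]
    assert auc["mean"] == 0.9 and auc["sd"] == 0.0
    assert auc["ci_lower"] == auc["ci_upper"] == 0.9


def test_aggregate_two_values_closed_form():
    auc = aggregate_repeats(metric_sets([0.8, 0.9])).metrics["auc"]
    assert auc["mean"] == pytest.approx(0.85)
    assert auc["sd"] == pytest.approx(np.std([0.8, 0.9], ddof=1))
    assert auc["sd"] == pytest.approx(0.0707, abs=1e-4)


def test_bootstrap_ci_brackets_mean():
    rng = np.random.default_rng(0)
    for _ in range(100):
        values = rng.random(rng.integers(2, 8))
        summary = aggregate_repeats(metric_sets(values), n_boot=2000, seed=1)
        auc = summary.metrics["auc"]
        assert auc["ci_lower"] <= auc["mean"] <= auc["ci_upper"]


def test_single_repeat_rejected():
    with pytest.raises(ValueError):
        aggregate_repeats(metric_sets([0.9]))


def test_wilcoxon_five_positive_differences():
    res = paired_wilcoxon([1, 2, 3, 4, 5], [0.5, 1.5, 2.5, 3.5, 4.5])
    assert res.p_one_sided == pytest.approx(1 / 32)
    assert res.p_two_sided == pytest.approx(1 / 16)
    assert res.statistic == 15.0


def test_wilcoxon_identical_inputs_degenerate():
    res = paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_one_sided == 1.0 and res.p_two_sided == 1.0
    assert res.n_effective == 0


def test_wilcoxon_sign_flip_swaps_tails():
    a = np.array([0.9, 0.8, 0.85, 0.95, 0.7])
    b = np.array([0.6, 0.75, 0.8, 0.7, 0.72])
    fwd = paired_wilcoxon(a, b)
    rev = paired_wilcoxon(b, a)
    assert fwd.p_two_sided == pytest.approx(rev.p_two_sided)
    # P(W >= w) one side + P(W <= w') other side partition the distribution
    assert fwd.p_one_sided < 0.5 < rev.p_one_sided


def test_wilcoxon_matches_scipy_exact_without_ties():
    from scipy.stats import wilcoxon as scipy_wilcoxon

    rng = np.random.default_rng(5)
    for _ in range(20):
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        ours = paired_wilcoxon(a, b)
        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue)


def test_confusion_matrix_counts():
    cm = confusion_matrix([0.9, 0.2, 0.7, 0.4], [1, 0, 0, 1])
    assert cm.loc["actual_PD", "pred_PD"] == 1
    assert cm.loc["actual_PD", "pred_CO"] == 1
    assert cm.loc["actual_CO", "pred_PD"] == 1
    assert cm.loc["actual_CO", "pred_CO"] == 1
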