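"""Metric-suite unit and property tests against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from beetlerisk.metrics import (
    ConfusionMatrix,
    backsolve_confusion,
    confusion,
    gleichlaeufigkeit,
    metric_report,
    select_threshold,
)


def brute_confusion(labels, preds):
    tp = tn = fp = fn = 0
    for y, p in zip(labels, preds):
        if y == 1 and p == 1:
            tp += 1
        elif y == 0 and p == 0:
            tn += 1
        elif y == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


class TestConfusion:
    def test_hand_examples(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 1, 0, 0)
        cm = confusion([1, 0], [0, 0])
        assert (cm.fn, cm.tn, cm.tp, cm.fp) == (1, 1, 0, 0)

    def test_matches_loop_tally_on_random_pairs(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, 1000)
        p = rng.integers(0, 2, 1000)
        cm = confusion(y, p)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == brute_confusion(y, p)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion([1, 0], [1])
        with pytest.raises(ValueError, match="non-binary"):
            confusion([1, 2], [1, 0])


class TestMetricReport:
    def test_perfect_classifier_scores_one_everywhere(self):
        rep = metric_report(ConfusionMatrix(tp=10, tn=90, fp=0, fn=0))
        for name in ("accuracy", "precision", "recall", "f1",
                     "conditional_kappa", "true_skill_statistic"):
            assert getattr(rep, name) == pytest.approx(1.0)

    def test_degenerate_cells_flagged_not_raised(self):
        # no predicted positives: precision undefined
        rep = metric_report(ConfusionMatrix(tp=0, tn=5, fp=0, fn=5))
        assert math.isnan(rep.precision)
        assert rep.accuracy == pytest.approx(0.5)

    def test_published_experiment1_matrix(self):
        # pooled year-holdout confusion matrix of the reference analysis
        rep = metric_report(ConfusionMatrix(tp=4771, fn=7401, fp=2547, tn=277840))
        assert rep.precision == pytest.approx(0.652, abs=0.005)
        assert rep.recall == pytest.approx(0.392, abs=0.005)
        assert rep.f1 == pytest.approx(0.490, abs=0.005)
        assert rep.conditional_kappa == pytest.approx(0.637, abs=0.005)
        assert rep.true_skill_statistic == pytest.approx(0.626, abs=0.005)

    def test_f1_is_harmonic_mean_of_reported_precision_recall(self):
        # direct check of the F1 identity at 3-decimal inputs
        p, r = 0.413, 0.411
        assert 2 * p * r / (p + r) == pytest.approx(0.412, abs=5e-4)

    @given(
        tp=st.integers(1, 10_000),
        tn=st.integers(1, 10_000),
        fp=st.integers(0, 10_000),
        fn=st.integers(0, 10_000),
    )
    def test_f1_harmonic_identity_property(self, tp, tn, fp, fn):
        rep = metric_report(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
        harmonic = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
        assert rep.f1 == pytest.approx(harmonic, rel=1e-12)

    @given(tp=st.integers(1, 1000), tn=st.integers(1, 1000),
           fp=st.integers(0, 1000), fn=st.integers(0, 1000))
    def test_kappa_and_tss_equal_one_iff_error_free(self, tp, tn, fp, fn):
        rep = metric_report(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
        if fp == 0 and fn == 0:
            assert rep.conditional_kappa == pytest.approx(1.0)
            assert rep.true_skill_statistic == pytest.approx(1.0)
        else:
            assert rep.conditional_kappa < 1.0
            assert rep.true_skill_statistic < 1.0

    def test_near_zero_under_label_shuffling(self):
        n = 10_000
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            labels = (rng.random(n) < 0.1).astype(int)
            shuffled = rng.permutation(labels)
            rep = metric_report(confusion(labels, shuffled))
            assert abs(rep.conditional_kappa) < 0.05
            assert abs(rep.true_skill_statistic) < 0.05


class TestBacksolve:
    def test_experiment1_prevalence(self):
        cm = backsolve_confusion(292_559, 0.966, 0.652, 0.392)
        assert cm.positives == pytest.approx(12_172, abs=5)
        assert cm.prevalence == pytest.approx(0.042, abs=0.001)

    def test_experiment2_prevalence_matches_study_imbalance(self):
        cm = backsolve_confusion(373_817, 0.959, 0.413, 0.411)
        assert cm.prevalence == pytest.approx(0.035, abs=0.001)

    def test_perfect_inputs_give_error_free_matrix(self):
        cm = backsolve_confusion(100, 1.0, 1.0, 1.0)
        assert cm.fp == 0 and cm.fn == 0

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            backsolve_confusion(100, 0.5, 1.0, 1.0)

    @given(tp=st.integers(1, 50_000), tn=st.integers(0, 500_000),
           fp=st.integers(0, 50_000), fn=st.integers(0, 50_000))
    def test_forward_backsolve_identity(self, tp, tn, fp, fn):
        if fp + fn == 0:
            return  # error-free matrices do not pin down prevalence
        cm = ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
        rep = metric_report(cm)
        back = backsolve_confusion(cm.n, rep.accuracy, rep.precision, rep.recall)
        assert (back.tp, back.tn, back.fp, back.fn) == (tp, tn, fp, fn)


def brute_threshold(probs, labels):
    """Exhaustive max-F1 search over all unique probabilities."""
    best_f1, best_t = -1.0, None
    for t in sorted(set(probs)):
        pred = (probs >= t).astype(int)
        tp = int(np.sum((labels == 1) & (pred == 1)))
        fp = int(np.sum((labels == 0) & (pred == 1)))
        fn = int(np.sum((labels == 1) & (pred == 0)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 >= best_f1:
            best_f1, best_t = f1, t
    return best_t, best_f1


class TestSelectThreshold:
    def test_separated_classes_tie_broken_upward(self):
        probs = np.array([0.1] * 5 + [0.9] * 5)
        labels = np.array([0] * 5 + [1] * 5)
        assert select_threshold(probs, labels) == pytest.approx(0.9)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(11)
        probs = np.round(rng.random(200), 3)  # grid-aligned probabilities
        labels = (rng.random(200) < probs).astype(int)
        t_grid = select_threshold(probs, labels)
        _, f1_brute = brute_threshold(probs, labels)
        pred = (probs >= t_grid).astype(int)
        tp = np.sum((labels == 1) & (pred == 1))
        fp = np.sum((labels == 0) & (pred == 1))
        fn = np.sum((labels == 1) & (pred == 0))
        f1_grid = 2 * tp / (2 * tp + fp + fn)
        assert f1_grid == pytest.approx(f1_brute, abs=1e-12)

    def test_constant_probabilities(self):
        probs = np.full(10, 0.7)
        labels = np.array([1, 0] * 5)
        t = select_threshold(probs, labels)
        assert t == pytest.approx(0.7)
        # F1 at that threshold equals the all-positive prediction's F1
        rep = metric_report(confusion(labels, np.ones(10, int)))
        assert rep.f1 == pytest.approx(2 * 5 / (2 * 5 + 5))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            select_threshold([0.2, 0.8], [1, 1])


def brute_gleichlaeufigkeit(x, y):
    def step_scores(v):
        out = []
        for a, b in zip(v[:-1], v[1:]):
            d = b - a
            out.append(0.5 if d > 0 else (-0.5 if d < 0 else 0.0))
        return out

    gx, gy = step_scores(list(x)), step_scores(list(y))
    return sum(abs(a + b) for a, b in zip(gx, gy)) / (len(x) - 1)


class TestGleichlaeufigkeit:
    def test_identical_monotone_series_scores_one(self):
        x = [1, 2, 3, 4, 5]
        assert gleichlaeufigkeit(x, x) == pytest.approx(1.0)

    def test_opposite_trends_score_zero(self):
        assert gleichlaeufigkeit([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert gleichlaeufigkeit([1, 2, 1, 3], [2, 1, 3, 4]) == pytest.approx(1 / 3)

    def test_matches_loop_oracle_on_random_series(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            assert gleichlaeufigkeit(x, y) == pytest.approx(brute_gleichlaeufigkeit(x, y))

    @given(st.lists(st.integers(-1000, 1000), min_size=2, max_size=20),
           st.integers(-100_000, 100_000))
    def test_symmetric_and_shift_invariant(self, x, c):
        y = list(reversed(x))
        g1 = gleichlaeufigkeit(x, y)
        assert g1 == pytest.approx(gleichlaeufigkeit(y, x))
        shifted = [v + c for v in x]
        assert gleichlaeufigkeit(shifted, y) == pytest.approx(g1)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            gleichlaeufigkeit([1], [2])
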