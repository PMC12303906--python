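import numpy as np
import pytest

from plaquenet.metrics import (
    ConfusionCounts,
    accuracy,
    confusion,
    dice,
    iou_excluding_background,
    miou,
    regression_metrics,
    seg_metrics,
)


def set_based_oracle(pred, true, num_classes=2):
    """Brute-force metrics via explicit pixel index sets."""
    pred, true = np.asarray(pred), np.asarray(true)
    all_px = pred.size
    correct = int((pred == true).sum())
    ious = []
    for c in range(num_classes):
        p = set(map(tuple, np.argwhere(pred == c)))
        t = set(map(tuple, np.argwhere(true == c)))
        union = p | t
        ious.append(1.0 if not union else len(p & t) / len(union))
    p = set(map(tuple, np.argwhere(pred != 0)))
    t = set(map(tuple, np.argwhere(true != 0)))
    d = 100.0 if not (p or t) else 100.0 * 2 * len(p & t) / (len(p) + len(t))
    return {
        "accuracy": 100.0 * correct / all_px,
        "miou": 100.0 * float(np.mean(ious)),
        "iou_fg": 100.0 * float(np.mean(ious[1:])),
        "dice": d,
    }


class TestConfusion:
    def test_all_plaque_agreement(self):
        m = np.ones((4, 4), dtype=int)
        c = confusion(m, m)
        assert (c.tp, c.fp, c.tn, c.fn) == (16, 0, 0, 0)

    def test_complement_masks(self):
        t = np.zeros((4, 4), dtype=int)
        t[:2] = 1
        c = confusion(1 - t, t)
        assert c.tp == 0 and c.tn == 0 and c.fp == 8 and c.fn == 8

    def test_counts_partition_pixels(self):
        rng = np.random.default_rng(0)
        p, t = rng.integers(0, 2, (16, 16)), rng.integers(0, 2, (16, 16))
        c = confusion(p, t)
        assert c.total == 256

    def test_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(1)
        p, t = rng.integers(0, 2, (16, 16)), rng.integers(0, 2, (16, 16))
        c = confusion(p, t)
        tp = fp = tn = fn = 0
        for i in range(16):
            for j in range(16):
                if p[i, j] and t[i, j]:
                    tp += 1
                elif p[i, j] and not t[i, j]:
                    fp += 1
                elif not p[i, j] and t[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.full((2, 2), 3), np.zeros((2, 2)), num_classes=2)


class TestSegMetricValues:
    def test_perfect_prediction(self):
        t = np.zeros((8, 8), dtype=int)
        t[2:5, 2:5] = 1
        c = confusion(t, t)
        m = seg_metrics(c)
        assert m.accuracy_pct == m.miou_pct == m.iou_fg_pct == m.dice_pct == 100.0

    def test_accuracy_hand_case(self):
        c = ConfusionCounts(tp=3, fp=1, tn=5, fn=1)
        assert accuracy(c) == pytest.approx(80.0)

    def test_four_pixel_enumerable_case(self):
        # pred all background, truth half plaque on 2x2
        pred = np.zeros((2, 2), dtype=int)
        true = np.array([[1, 1], [0, 0]])
        c = confusion(pred, true)
        assert miou(c) == pytest.approx(25.0)
        assert iou_excluding_background(c) == pytest.approx(0.0)

    def test_dice_hand_case(self):
        c = ConfusionCounts(tp=2, fp=1, tn=0, fn=1,
                            per_class=((0, 1, 1), (2, 1, 1)))
        assert dice(c) == pytest.approx(100 * 4 / 6)

    def test_disjoint_nonempty_masks_give_zero_dice(self):
        p = np.array([[1, 0], [0, 0]])
        t = np.array([[0, 0], [0, 1]])
        assert dice(confusion(p, t)) == 0.0

    def test_absent_class_counts_as_perfect(self):
        both_bg = np.zeros((3, 3), dtype=int)
        c = confusion(both_bg, both_bg)
        assert miou(c) == 100.0
        assert dice(c) == 100.0


class TestOracleEquivalence:
    def test_matches_set_based_oracle_on_random_masks(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            h, w = rng.integers(2, 32, 2)
            p = (rng.random((h, w)) < rng.uniform(0, 1)).astype(int)
            t = (rng.random((h, w)) < rng.uniform(0, 1)).astype(int)
            c = confusion(p, t)
            ref = set_based_oracle(p, t)
            assert accuracy(c) == pytest.approx(ref["accuracy"], abs=1e-12)
            assert miou(c) == pytest.approx(ref["miou"], abs=1e-12)
            assert iou_excluding_background(c) == pytest.approx(ref["iou_fg"], abs=1e-12)
            assert dice(c) == pytest.approx(ref["dice"], abs=1e-12)

    def test_dice_iou_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.integers(0, 2, (12, 12))
            t = rng.integers(0, 2, (12, 12))
            c = confusion(p, t)
            i = iou_excluding_background(c) / 100
            assert dice(c) == pytest.approx(100 * 2 * i / (1 + i), abs=1e-9)

    def test_spatial_permutation_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.integers(0, 2, (10, 10))
        t = rng.integers(0, 2, (10, 10))
        perm = rng.permutation(100)
        ps = p.ravel()[perm].reshape(10, 10)
        ts = t.ravel()[perm].reshape(10, 10)
        assert seg_metrics(confusion(p, t)) == seg_metrics(confusion(ps, ts))


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        r = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mse == 0 and r.mae == 0 and r.r2 == 1.0

    def test_mean_predictor_gives_zero_r2(self):
        truth = np.array([1.0, 2.0, 3.0, 4.0])
        r = regression_metrics(np.full(4, truth.mean()), truth)
        assert r.r2 == pytest.approx(0.0)

    def test_three_point_hand_case(self):
        r = regression_metrics([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        assert r.mse == pytest.approx(1 / 3)
        assert r.mae == pytest.approx(1 / 3)
        assert r.r2 == pytest.approx(0.5)

    def test_zero_variance_truth_warns_and_reports_missing(self):
        with pytest.warns(UserWarning):
            r = regression_metrics([1.0, 2.0], [3.0, 3.0])
        assert r.r2 is None

    def test_r2_never_exceeds_one(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p, t = rng.normal(size=8), rng.normal(size=8)
            r = regression_metrics(p, t)
            assert r.r2 <= 1.0
            assert r.mse >= 0 and r.mae >= 0


class TestHypothesisProperties:
    """Randomized invariants via hypothesis (derandomized for CI stability)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    masks = arrays(np.int8, (6, 6), elements=st.integers(0, 1))

    @staticmethod
    @given(p=masks, t=masks)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_confusion_partitions_and_dice_iou_identity(p, t):
        c = confusion(p, t)
        assert c.total == p.size
        i = iou_excluding_background(c) / 100
        assert dice(c) == pytest.approx(100 * 2 * i / (1 + i), abs=1e-9)

    @staticmethod
    @given(p=masks, t=masks)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_symmetry_of_dice_and_bounds(p, t):
        a, b = confusion(p, t), confusion(t, p)
        assert dice(a) == pytest.approx(dice(b), abs=1e-12)
        for v in (accuracy(a), miou(a), dice(a), iou_excluding_background(a)):
            assert 0.0 <= v <= 100.0
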