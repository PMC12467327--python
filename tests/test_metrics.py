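import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ascseg.metrics import (MetricsResult, confusion_counts, dsc, iou,
                            dsc_from_counts, iou_from_counts, difference_map,
                            render_difference_map, dsc_fp_sensitivity,
                            DIFFERENCE_CATEGORIES)

masks = st.integers(0, 2**16 - 1).map(
    lambda seed: np.random.default_rng(seed).integers(0, 2, size=(8, 8)))


class TestConfusionCounts:
    def test_perfect_agreement(self):
        ones = np.ones((2, 2), dtype=int)
        assert confusion_counts(ones, ones) == (4, 0, 0, 0)

    def test_complement_has_no_true_pixels(self):
        g = np.array([[1, 0], [0, 1]])
        tp, fp, fn, tn = confusion_counts(1 - g, g)
        assert tp == 0 and tn == 0 and fp == 2 and fn == 2

    def test_matches_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(0)
        p, g = rng.integers(0, 2, (16, 16)), rng.integers(0, 2, (16, 16))
        tp = sum(int(p[i, j] == 1 and g[i, j] == 1) for i in range(16) for j in range(16))
        fp = sum(int(p[i, j] == 1 and g[i, j] == 0) for i in range(16) for j in range(16))
        fn = sum(int(p[i, j] == 0 and g[i, j] == 1) for i in range(16) for j in range(16))
        tn = 256 - tp - fp - fn
        assert confusion_counts(p, g) == (tp, fp, fn, tn)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_counts(np.full((2, 2), 2), np.zeros((2, 2)))


class TestOverlapMetrics:
    def test_identical_non_empty_masks_score_one(self):
        m = np.eye(4, dtype=int)
        assert dsc(m, m) == 1.0
        assert iou(m, m) == 1.0

    def test_count_formula_example(self):
        # TP=2, FP=1, FN=1
        assert dsc_from_counts(2, 1, 1) == pytest.approx(4 / 6)
        assert iou_from_counts(2, 1, 1) == pytest.approx(0.5)

    def test_disjoint_non_empty_masks_score_zero(self):
        p = np.zeros((2, 2), dtype=int); p[0, 0] = 1
        g = np.zeros((2, 2), dtype=int); g[1, 1] = 1
        assert dsc(p, g) == 0.0
        assert iou(p, g) == 0.0

    def test_empty_vs_empty_convention(self):
        z = np.zeros((3, 3), dtype=int)
        assert dsc(z, z) == 1.0
        assert iou(z, z) == 1.0

    def test_empty_vs_non_empty_is_zero(self):
        z = np.zeros((3, 3), dtype=int)
        assert dsc(z, np.ones_like(z)) == 0.0

    @given(p=masks, g=masks)
    @settings(max_examples=80, deadline=None)
    def test_dice_iou_identity_and_ordering(self, p, g):
        d, j = dsc(p, g), iou(p, g)
        assert d >= j
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
        if d in (0.0, 1.0):
            assert d == j

    @given(p=masks, g=masks)
    @settings(max_examples=40, deadline=None)
    def test_symmetry_under_swapping(self, p, g):
        assert dsc(p, g) == pytest.approx(dsc(g, p), abs=0)
        assert iou(p, g) == pytest.approx(iou(g, p), abs=0)

    def test_metrics_result_bookkeeping(self):
        rng = np.random.default_rng(1)
        p, g = rng.integers(0, 2, (8, 8)), rng.integers(0, 2, (8, 8))
        m = MetricsResult.from_masks(p, g)
        assert m.N == 64
        assert m.TP + m.FP + m.FN + m.TN == m.N
        assert m.dsc == dsc(p, g)


class TestDifferenceMap:
    def test_agreement_has_only_tn_tp(self):
        m = np.eye(4, dtype=int)
        cats = set(np.unique(difference_map(m, m)))
        assert cats <= {DIFFERENCE_CATEGORIES["TN"], DIFFERENCE_CATEGORIES["TP"]}

    def test_category_histogram_equals_confusion_counts(self):
        rng = np.random.default_rng(2)
        p, g = rng.integers(0, 2, (12, 12)), rng.integers(0, 2, (12, 12))
        cat = difference_map(p, g)
        tp, fp, fn, tn = confusion_counts(p, g)
        assert (cat == DIFFERENCE_CATEGORIES["TP"]).sum() == tp
        assert (cat == DIFFERENCE_CATEGORIES["FP"]).sum() == fp
        assert (cat == DIFFERENCE_CATEGORIES["FN"]).sum() == fn
        assert (cat == DIFFERENCE_CATEGORIES["TN"]).sum() == tn

    def test_all_false_positive_renders_red(self):
        p = np.ones((2, 2), dtype=int)
        g = np.zeros((2, 2), dtype=int)
        rgb = render_difference_map(difference_map(p, g))
        assert (rgb == [255, 0, 0]).all()

    def test_legend_colors(self):
        cat = np.array([[0, 1], [2, 3]])
        rgb = render_difference_map(cat)
        assert rgb[0, 0].tolist() == [0, 0, 0]        # TN black
        assert rgb[0, 1].tolist() == [255, 255, 255]  # TP white
        assert rgb[1, 0].tolist() == [0, 0, 255]      # FN blue
        assert rgb[1, 1].tolist() == [255, 0, 0]      # FP red


class TestDscFpSensitivity:
    def test_direct_evaluation(self):
        assert dsc_fp_sensitivity(1, 0, 0) == pytest.approx(-0.5)

    def test_zero_tp_gives_zero_slope(self):
        assert dsc_fp_sensitivity(0, 5, 0) == 0.0

    def test_undefined_for_all_zero_counts(self):
        with pytest.raises(ValueError):
            dsc_fp_sensitivity(0, 0, 0)

    @given(tp=st.integers(1, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
    @settings(max_examples=80, deadline=None)
    def test_sensitivity_non_positive_and_matches_finite_difference(self, tp, fp, fn):
        s = dsc_fp_sensitivity(tp, fp, fn)
        assert s <= 0.0
        delta = dsc_from_counts(tp, fp + 1, fn) - dsc_from_counts(tp, fp, fn)
        assert delta <= 0.0  # adding a false positive never raises DSC
        denom = 2 * tp + fp + fn
        assert abs(delta - s) <= 4.0 / denom**2
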