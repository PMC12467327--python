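import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ascseg.asc import ASCConfig, build_enhancement_map, apply_enhancement, enhance_step, default_factor


def brute_force_map(prediction, cfg):
    """Independent double-loop oracle for the kernel-value rule."""
    pred = np.asarray(prediction, dtype=float)
    if cfg.binarize_first:
        pred = (pred > 0.5).astype(float)
    H, W = pred.shape
    ks = cfg.kernel_size
    out = np.empty((H, W))
    for i0 in range(0, H, ks):
        for j0 in range(0, W, ks):
            total = 0.0
            for i in range(i0, min(i0 + ks, H)):
                for j in range(j0, min(j0 + ks, W)):
                    total += pred[i, j]
            mean = total / (ks * ks)  # zero-padded boundary kernels
            val = cfg.factor if mean > cfg.epsilon else 1.0
            for i in range(i0, min(i0 + ks, H)):
                for j in range(j0, min(j0 + ks, W)):
                    out[i, j] = val
    return out


class TestBuildEnhancementMap:
    def test_all_zero_prediction_gives_identity_map(self):
        cfg = ASCConfig(16, 0.5, 1.4)
        assert (build_enhancement_map(np.zeros((32, 32)), cfg) == 1.0).all()

    def test_all_one_prediction_enhances_everywhere(self):
        cfg = ASCConfig(16, 0.5, 1.4)
        assert (build_enhancement_map(np.ones((32, 32)), cfg) == 1.4).all()

    def test_single_filled_kernel(self):
        pred = np.zeros((32, 32))
        pred[:16, :16] = 1.0
        e_m = build_enhancement_map(pred, ASCConfig(16, 0.5, 1.4))
        assert (e_m[:16, :16] == 1.4).all()
        assert (e_m[:16, 16:] == 1.0).all()
        assert (e_m[16:, :] == 1.0).all()

    def test_kernel_mean_exactly_at_threshold_not_enhanced(self):
        # mean over one 4x4 kernel is exactly epsilon: strict '>' keeps 1.0
        pred = np.zeros((4, 4))
        pred[:2] = 1.0  # mean 0.5
        e_m = build_enhancement_map(pred, ASCConfig(4, 0.5, 1.4))
        assert (e_m == 1.0).all()
        e_m = build_enhancement_map(pred, ASCConfig(4, 0.4999, 1.4))
        assert (e_m == 1.4).all()

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for ks in (4, 8, 16, 32):
            for eps in (0.0, 0.25, 0.5):
                for ef in (1.0, 1.1, 1.4):
                    for _ in range(3):
                        H = int(rng.integers(8, 48))
                        W = int(rng.integers(8, 48))
                        pred = rng.random((H, W))
                        cfg = ASCConfig(ks, eps, ef)
                        np.testing.assert_array_equal(
                            build_enhancement_map(pred, cfg),
                            brute_force_map(pred, cfg))
                        checked += 1
        assert checked >= 100

    def test_map_values_form_two_element_set(self):
        rng = np.random.default_rng(5)
        cfg = ASCConfig(8, 0.25, 1.1)
        e_m = build_enhancement_map(rng.random((40, 24)), cfg)
        assert set(np.unique(e_m)) <= {1.0, cfg.factor}

    def test_enhanced_area_multiple_of_kernel_area_when_divisible(self):
        rng = np.random.default_rng(6)
        cfg = ASCConfig(8, 0.25, 1.4)
        e_m = build_enhancement_map(rng.random((32, 32)), cfg)
        assert int((e_m == 1.4).sum()) % (8 * 8) == 0

    def test_binarize_first_option(self):
        pred = np.full((4, 4), 0.6)  # binarizes to all-ones
        cfg = ASCConfig(4, 0.5, 1.4, binarize_first=True)
        assert (build_enhancement_map(pred, cfg) == 1.4).all()

    def test_non_finite_prediction_rejected(self):
        pred = np.zeros((8, 8))
        pred[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            build_enhancement_map(pred, ASCConfig(4, 0.5, 1.4))

    @pytest.mark.parametrize("kw", [dict(kernel_size=0), dict(epsilon=-0.1),
                                    dict(factor=0.9)])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            ASCConfig(**{"kernel_size": 16, "epsilon": 0.5, "factor": 1.1, **kw})


class TestApplyEnhancement:
    def test_identity_map_is_bitwise_identity(self):
        x = np.random.default_rng(0).random((16, 16))
        out = apply_enhancement(x, np.ones_like(x))
        assert np.array_equal(out, x)

    def test_pixel_value_scales_by_factor(self):
        out = apply_enhancement(np.array([[0.5]]), np.array([[1.4]]))
        assert out[0, 0] == pytest.approx(0.7)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(1)
        x, e = rng.random((8, 8)), 1 + 0.4 * rng.random((8, 8))
        out = apply_enhancement(x, e)
        for i in range(8):
            for j in range(8):
                assert out[i, j] == x[i, j] * e[i, j]

    def test_no_clipping_above_one(self):
        out = apply_enhancement(np.array([[0.9]]), np.array([[1.4]]))
        assert out[0, 0] > 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            apply_enhancement(np.zeros((4, 4)), np.ones((8, 8)))


class TestEnhanceStep:
    def test_zero_prediction_returns_slice_unchanged(self):
        x = np.random.default_rng(3).random((32, 32))
        out = enhance_step(np.zeros((32, 32)), x, ASCConfig(16, 0.5, 1.4))
        assert np.array_equal(out, x)

    def test_confident_prediction_scales_every_pixel(self):
        x = np.random.default_rng(4).random((32, 32))
        out = enhance_step(np.ones((32, 32)), x, ASCConfig(16, 0.5, 1.1))
        np.testing.assert_allclose(out, x * 1.1)

    def test_composition_equals_two_step_oracle(self):
        rng = np.random.default_rng(7)
        pred, x = rng.random((24, 24)), rng.random((24, 24))
        cfg = ASCConfig(8, 0.25, 1.4)
        expected = apply_enhancement(x, brute_force_map(pred, cfg))
        np.testing.assert_array_equal(enhance_step(pred, x, cfg), expected)

    def test_epsilon_at_or_above_one_is_identity(self):
        rng = np.random.default_rng(8)
        x = rng.random((16, 16))
        for pred in (np.ones((16, 16)), rng.random((16, 16))):
            out = enhance_step(pred, x, ASCConfig(4, 1.0, 1.4))
            assert np.array_equal(out, x)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_the_image(self, seed):
        # raising one input pixel never lowers the corresponding output pixel
        rng = np.random.default_rng(seed)
        pred, x = rng.random((8, 8)), rng.random((8, 8))
        cfg = ASCConfig(4, 0.5, 1.4)
        base = enhance_step(pred, x, cfg)
        i, j = rng.integers(0, 8, size=2)
        x2 = x.copy()
        x2[i, j] += 0.5
        assert enhance_step(pred, x2, cfg)[i, j] >= base[i, j]


def test_default_factors_by_level():
    assert default_factor(1) == 1.1
    assert default_factor(2) == 1.4
    with pytest.raises(ValueError):
        default_factor(3)
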