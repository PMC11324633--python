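"""Evaluation metrics: hand-computable values, invariances, the
optimal-iteration rule and paired significance testing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spectsub.metrics import (
    DegenerateTestWarning,
    StabilizationWarning,
    arc,
    contrast_cnr,
    noise,
    optimal_iteration,
    paired_test,
    tn_ratio,
    true_voi_means,
    volume_metrics,
)
from spectsub.phantom import build_phantom_pair, build_voi_masks, default_config


def _img(values):
    return np.asarray(values, dtype=float).reshape(-1, 1, 1)


def _mask(n, on=None):
    m = np.zeros((n, 1, 1), dtype=bool)
    m[: n if on is None else on] = True
    return m


class TestArc:
    def test_perfect_recovery_is_100(self):
        img = _img([2.0, 2.0, 2.0])
        assert arc(img, _mask(3), 2.0) == pytest.approx(100.0)

    def test_half_intensity_is_50(self):
        img = _img([1.0, 1.0])
        assert arc(img, _mask(2), 2.0) == pytest.approx(50.0)

    def test_hand_computed_value(self):
        # mean {1,2,3} = 2 against a true mean of 4 -> 50%
        assert arc(_img([1.0, 2.0, 3.0]), _mask(3), 4.0) == pytest.approx(50.0)

    def test_scales_linearly_with_image(self):
        img = _img([1.0, 2.0, 5.0])
        assert arc(3 * img, _mask(3), 2.0) == pytest.approx(3 * arc(img, _mask(3), 2.0))

    def test_empty_mask_and_bad_truth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            arc(_img([1.0]), np.zeros((1, 1, 1), dtype=bool), 1.0)
        with pytest.raises(ValueError, match="true_mean"):
            arc(_img([1.0]), _mask(1), 0.0)


class TestNoise:
    def test_constant_background_is_zero(self):
        assert noise(_img([3.0, 3.0, 3.0]), _mask(3)) == 0.0

    def test_two_point_closed_form(self):
        # {1, 3}: mean 2, sd sqrt(2) -> 0.7071
        assert noise(_img([1.0, 3.0]), _mask(2)) == pytest.approx(0.70710678, abs=1e-8)

    @pytest.mark.parametrize("c", [0.5, 2.0, 117.0])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        img = rng.random((30, 1, 1)) + 0.5
        assert noise(c * img, _mask(30)) == pytest.approx(noise(img, _mask(30)))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            noise(_img([-1.0, 1.0]), _mask(2))


class TestContrastCnr:
    def test_equal_means_give_zero(self):
        img = _img([2.0, 2.0, 2.0, 2.1, 1.9])
        tumor = _mask(5, 3)
        bg = ~tumor
        c, r = contrast_cnr(img, tumor, bg)
        assert c == pytest.approx((2.0 - 2.0) / 2.0)

    def test_hand_computed_values(self):
        # tumor mean 4, bg mean 1, bg noise 0.5 -> contrast 3, CNR 6
        img = np.zeros((4, 1, 1))
        img[0] = 4.0
        img[1:] = [[[0.5]], [[1.0]], [[1.5]]]
        tumor = _mask(4, 1)
        bg = ~tumor
        c, r = contrast_cnr(img, tumor, bg)
        assert c == pytest.approx(3.0)
        assert r == pytest.approx(6.0)

    def test_noiseless_nonzero_contrast_rejected(self):
        img = _img([4.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="noise is zero"):
            contrast_cnr(img, _mask(4, 1), ~_mask(4, 1))


class TestTnRatio:
    def test_uniform_image_is_one(self):
        img = _img([2.0] * 6)
        assert tn_ratio(img, _mask(6, 2), ~_mask(6, 2)) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        img = np.concatenate([np.full((2, 1, 1), 5.0), np.full((3, 1, 1), 2.0)])
        assert tn_ratio(img, _mask(5, 2), ~_mask(5, 2)) == pytest.approx(2.5)

    @pytest.mark.parametrize("c", [0.1, 7.0])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(1)
        img = rng.random((20, 1, 1)) + 0.2
        t, b = _mask(20, 5), ~_mask(20, 5)
        assert tn_ratio(c * img, t, b) == pytest.approx(tn_ratio(img, t, b))


@pytest.fixture(scope="module")
def phantom():
    cfg = default_config("full")
    pre, post, diff = build_phantom_pair(cfg)
    masks = build_voi_masks(cfg)
    return cfg, diff, masks


class TestGroundTruthPhantomMetrics:
    """On the noise-free phantom the configured ratios are recovered exactly
    and every VOI sits at 100% recovery."""

    def test_true_difference_tn_is_four(self, phantom):
        cfg, diff, masks = phantom
        assert tn_ratio(
            diff.values, masks.tumor_masks[0], masks.background_mask
        ) == pytest.approx(4.0, rel=0.02)

    def test_true_contrast_is_three(self, phantom):
        cfg, diff, masks = phantom
        truths = true_voi_means(diff, masks)
        rows = {r["voi"]: r for r in volume_metrics(diff.values, masks, truths)}
        assert rows["tumor_1"]["contrast"] == pytest.approx(3.0, rel=0.02)

    def test_all_vois_recover_100_percent(self, phantom):
        cfg, diff, masks = phantom
        truths = true_voi_means(diff, masks)
        for r in volume_metrics(diff.values, masks, truths):
            assert r["arc"] == pytest.approx(100.0, rel=1e-9)


class TestOptimalIteration:
    def test_constant_series_stops_at_two(self):
        curves = np.tile([50.0, 50.0, 50.0, 50.0], (1, 1)).T
        assert optimal_iteration(np.column_stack([curves])) == 2

    def test_hand_worked_two_voi_series(self):
        tumors = [70.0, 78.0, 78.5, 78.9]
        background = [95.0, 99.0, 99.5, 99.8]
        assert optimal_iteration(np.column_stack([tumors, background])) == 3

    def test_never_stabilizing_returns_last_with_warning(self):
        curves = np.cumsum(np.full((25, 1), 2.0), axis=0)
        with pytest.warns(StabilizationWarning):
            assert optimal_iteration(curves) == 25

    def test_needs_two_iterations(self):
        with pytest.raises(ValueError, match="two iterations"):
            optimal_iteration(np.array([[100.0]]))

    def test_non_monotone_change_counts_as_unstable(self):
        # |change| is what matters, a -3 swing is not stabilization
        curves = np.array([[90.0], [93.0], [90.0], [90.2]])
        assert optimal_iteration(curves) == 4


class TestPairedTest:
    def test_identical_vectors_give_p_one(self):
        assert paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_constant_shift_is_degenerate(self):
        with pytest.warns(DegenerateTestWarning):
            assert paired_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]) == 0.0

    def test_matches_closed_form_t_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.1, 2.9, 4.2, 4.8])
        d = b - a
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        expected = 2.0 * stats.t.sf(abs(t), len(d) - 1)
        assert paired_test(b, a) == pytest.approx(expected, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_test([1.0, 2.0], [1.0])


class TestInvariantsProperty:
    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    def test_cnr_is_contrast_over_noise_and_scale_free(self, seed, c):
        rng = np.random.default_rng(seed)
        img = rng.random((40, 1, 1)) + 0.1
        tumor = _mask(40, 8)
        bg = ~tumor
        contrast, cnr = contrast_cnr(img, tumor, bg)
        assert cnr == pytest.approx(contrast / noise(img, bg))
        c2, cnr2 = contrast_cnr(c * img, tumor, bg)
        assert cnr2 == pytest.approx(cnr, rel=1e-9)
        # ARC is *not* scale invariant
        assert arc(c * img, tumor, 1.0) == pytest.approx(c * arc(img, tumor, 1.0))
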