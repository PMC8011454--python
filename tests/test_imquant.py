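"""Projection, threshold masking, histogram, rolling ball, Pearson/Manders."""

import numpy as np
import pytest

import hnslab as H
from hnslab.imquant import (
    EmptyMaskError,
    costes_thresholds,
    group_compare,
    intensity_histogram,
    manders_coloc,
    normalized_area_metric,
    pearson_coloc,
    rolling_ball_background,
    sum_projection,
    threshold_mask,
)


class TestSumProjection:
    def test_constant_slices(self):
        stack = np.full((3, 4, 5), 7.0)
        np.testing.assert_allclose(sum_projection(stack), 21.0)

    def test_single_slice_identity(self):
        rng = np.random.default_rng(61)
        img = rng.uniform(0, 100, (1, 8, 8))
        np.testing.assert_allclose(sum_projection(img), img[0])

    def test_matches_elementwise_sum_and_linearity(self):
        rng = np.random.default_rng(62)
        s1 = rng.uniform(0, 50, (5, 16, 16))
        s2 = rng.uniform(0, 50, (5, 16, 16))
        np.testing.assert_allclose(sum_projection(s1), np.sum(s1, axis=0))
        np.testing.assert_allclose(
            sum_projection(2 * s1 + 3 * s2),
            2 * sum_projection(s1) + 3 * sum_projection(s2))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            sum_projection(np.zeros((4, 4)))


class TestThresholdMask:
    def test_all_below_gives_empty_mask(self):
        with pytest.warns(UserWarning, match="empty"):
            masked = threshold_mask(np.full((4, 4), 5.0), 10.0)
        assert masked.n_masked == 0

    def test_strict_inequality_at_boundary(self):
        proj = np.array([[399.0, 400.0, 401.0]])
        masked = threshold_mask(proj, 400.0)
        assert masked.n_masked == 1
        assert masked.masked_values[0] == 401.0

    def test_retained_count_matches_counting_oracle(self):
        rng = np.random.default_rng(63)
        proj = rng.uniform(0, 200, (32, 32))
        masked = threshold_mask(proj, 128.0)
        assert masked.n_masked == int((proj > 128.0).sum())


class TestHistogram:
    def test_unit_bins(self):
        proj = np.array([[401.0, 401.0, 402.0, 0.0]])
        masked = threshold_mask(proj, 400.0)
        edges, counts = intensity_histogram(masked)
        assert list(counts) == [2, 1]
        assert edges[0] == 401.0

    def test_counts_conserved(self):
        rng = np.random.default_rng(64)
        proj = rng.uniform(0, 300, (20, 20))
        masked = threshold_mask(proj, 128.0)
        _, counts = intensity_histogram(masked)
        assert counts.sum() == masked.n_masked

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(65)
        proj = rng.uniform(100, 110, (16, 16))
        masked = threshold_mask(proj, 100.0)
        edges, counts = intensity_histogram(masked)
        for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            vals = masked.masked_values
            expect = ((vals >= lo) & (vals < hi)).sum()
            if k == len(counts) - 1:  # numpy closes the last bin
                expect = ((vals >= lo) & (vals <= hi)).sum()
            assert counts[k] == expect

    def test_empty_mask_rejected(self):
        with pytest.warns(UserWarning):
            masked = threshold_mask(np.zeros((4, 4)), 1.0)
        with pytest.raises(EmptyMaskError):
            intensity_histogram(masked)


class TestAreaMetric:
    def test_hand_computed(self):
        proj = np.full((10, 10), 50.0)
        masked = threshold_mask(proj, 10.0)
        assert normalized_area_metric(masked) == pytest.approx(100 / 50.0)

    def test_intensity_doubling_halves_metric(self):
        rng = np.random.default_rng(66)
        proj = rng.uniform(50, 150, (12, 12))
        m1 = threshold_mask(proj, 10.0)
        m2 = threshold_mask(proj * 2, 10.0)
        assert m1.mask.sum() == m2.mask.sum()  # same mask at this threshold
        assert normalized_area_metric(m2) == pytest.approx(
            normalized_area_metric(m1) / 2.0)


class TestGroupCompare:
    def test_identical_groups_one_tailed_half(self):
        out = group_compare([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(0.5)

    def test_paired_identical_zero_t(self):
        out = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert out["t"] == 0.0

    def test_unpaired_matches_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        out = group_compare(a, b, one_tailed=False)
        # pooled-variance t for equal n
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        t_expect = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * 2 / 3)
        assert out["t"] == pytest.approx(t_expect)

    def test_paired_requires_equal_n(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], [1, 2], paired=True)


class TestRollingBall:
    def test_constant_image_flattened(self):
        out = rolling_ball_background(np.full((32, 32), 40.0), 5)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_punctum_survives_background_removal(self):
        yy, xx = np.mgrid[0:64, 0:64]
        punctum = 100.0 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 2.0**2))
        img = 30.0 + punctum
        out = rolling_ball_background(img, 15)
        assert out.max() == pytest.approx(100.0, rel=0.10)
        assert out[0, 0] == pytest.approx(0.0, abs=1.0)

    def test_never_negative_and_radius_validated(self):
        rng = np.random.default_rng(67)
        img = rng.uniform(0, 100, (32, 32))
        assert rolling_ball_background(img, 4).min() >= 0.0
        with pytest.raises(ValueError):
            rolling_ball_background(img, 100)


class TestPearson:
    def test_identity_and_anticorrelation(self):
        rng = np.random.default_rng(68)
        a = rng.uniform(0, 100, (16, 16))
        assert pearson_coloc(a, a) == pytest.approx(1.0)
        assert pearson_coloc(a, -a + 50.0) == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(69)
        a = rng.uniform(0, 100, (16, 16))
        b = rng.uniform(0, 100, (16, 16))
        r0 = pearson_coloc(a, b)
        assert pearson_coloc(3.0 * a + 7.0, b) == pytest.approx(r0)

    def test_matches_direct_covariance_formula(self):
        stack, _ = H.simulate_coloc_stack(H.ColocSimParams(seed=70))
        a, b = stack[0].ravel(), stack[1].ravel()
        expect = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
        assert pearson_coloc(stack[0], stack[1]) == pytest.approx(expect)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_coloc(np.ones((4, 4)), np.random.default_rng(0).uniform(0, 1, (4, 4)))


class TestManders:
    def test_identical_channels_full_overlap(self):
        stack, _ = H.simulate_coloc_stack(
            H.ColocSimParams(overlap_fraction=1.0, background_level=0, noise_sd=0, seed=71))
        res = manders_coloc(stack[0], stack[0])
        assert res.r_p == pytest.approx(1.0)
        assert res.tm1 == pytest.approx(1.0, abs=0.05)
        assert res.tm1 == pytest.approx(res.tm2, abs=1e-9)

    def test_disjoint_puncta_near_zero(self):
        stack, _ = H.simulate_coloc_stack(H.ColocSimParams(
            overlap_fraction=0.0, n_puncta=12, background_level=0, noise_sd=0,
            min_separation_px=10.0, seed=72))
        res = manders_coloc(stack[0], stack[1])
        assert res.tm1 <= 0.05
        assert res.tm2 <= 0.05

    def test_half_overlap_recovered(self):
        stack, truth = H.simulate_coloc_stack(
            H.ColocSimParams(overlap_fraction=0.5, seed=73))
        res = manders_coloc(stack[0], stack[1])
        assert res.tm1 == pytest.approx(truth["overlap_fraction"], abs=0.1)

    def test_tm_bounded_and_monotone_in_threshold(self):
        stack, _ = H.simulate_coloc_stack(H.ColocSimParams(seed=74))
        a, b = stack[0], stack[1]
        last = 1.1
        for t2 in (0.0, 5.0, 50.0, 500.0):
            res = manders_coloc(a, b, thresholds=(5.0, t2))
            assert 0.0 <= res.tm1 <= 1.0 and 0.0 <= res.tm2 <= 1.0
            assert res.tm1 <= last + 1e-12
            last = res.tm1

    def test_manual_thresholds_respected(self):
        stack, _ = H.simulate_coloc_stack(H.ColocSimParams(seed=75))
        res = manders_coloc(stack[0], stack[1], thresholds=(10.0, 20.0))
        assert res.threshold_ch1 == 10.0 and res.threshold_ch2 == 20.0

    def test_all_zero_channel_rejected(self):
        with pytest.raises(ValueError):
            manders_coloc(np.zeros((4, 4)), np.ones((4, 4)))


def test_costes_identical_channels_floor_threshold():
    stack, _ = H.simulate_coloc_stack(
        H.ColocSimParams(background_level=0, noise_sd=0, seed=76))
    t1, t2 = costes_thresholds(stack[0], stack[0])
    assert t1 == pytest.approx(t2)
    assert t1 <= 0.01 * stack[0].max()  # near the intensity floor
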