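"""Wavelet transform identities, shrinkage algebra and threshold selectors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctdenoise import (
    ShrinkageRule,
    bayes_threshold,
    decompose,
    estimate_sigma,
    reconstruct,
    shrink,
    shrink_decomposition,
    universal_threshold,
)

finite = st.floats(-50, 50, allow_nan=False)
lam_st = st.floats(0, 10, allow_nan=False)
a_st = st.floats(0, 1, allow_nan=False)


class TestTransform:
    def test_haar_2x2_closed_form(self):
        # Hand derivation with the orthonormal Haar pair h = [1,1]/sqrt(2),
        # g = [-1,1]/sqrt(2), rows first then columns.
        a, b, c, d = 1.0, 2.0, 3.0, 4.0
        dec = decompose(np.array([[a, b], [c, d]]), "haar", 1)
        cH, cV, cD = dec.details[0]
        assert dec.approximation[0, 0] == pytest.approx((a + b + c + d) / 2)
        assert cH[0, 0] == pytest.approx((a + b - c - d) / 2)
        assert cV[0, 0] == pytest.approx((a - b + c - d) / 2)
        assert cD[0, 0] == pytest.approx((a - b - c + d) / 2)

    def test_constant_image_has_vanishing_details(self):
        dec = decompose(np.full((32, 32), 0.7), "db4", 1)
        for band in dec.details[0]:
            assert np.max(np.abs(band)) < 1e-10
        assert np.allclose(dec.approximation, dec.approximation.flat[0])

    @pytest.mark.parametrize("wavelet", ["haar", "db2", "db4", "sym8"])
    @pytest.mark.parametrize("mode", ["symmetric", "periodization", "reflect"])
    @pytest.mark.parametrize("shape", [(32, 32), (33, 47), (64, 40)])
    def test_perfect_reconstruction(self, rng, wavelet, mode, shape):
        import pywt

        img = rng.random(shape)
        levels = min(2, pywt.dwtn_max_level(shape, pywt.Wavelet(wavelet)))
        dec = decompose(img, wavelet, levels, mode)
        assert np.max(np.abs(reconstruct(dec) - img)) < 1e-8

    def test_synthesis_linearity(self, rng):
        img = rng.random((40, 40))
        dec = decompose(img, "db4", 2)
        dec.approximation = dec.approximation * 2
        dec.details = [tuple(b * 2 for b in t) for t in dec.details]
        assert np.max(np.abs(reconstruct(dec) - 2 * img)) < 1e-8

    def test_zeroed_subbands_give_zero_image(self, rng):
        dec = decompose(rng.random((32, 32)), "db4", 2)
        dec.approximation = np.zeros_like(dec.approximation)
        dec.details = [tuple(np.zeros_like(b) for b in t) for t in dec.details]
        assert np.max(np.abs(reconstruct(dec))) == 0.0

    def test_subband_shapes_follow_halving_cascade(self):
        # For non-periodized modes each DWT stage yields floor((n+L-1)/2)
        # coefficients for filter length L.
        import pywt

        for shape in [(64, 64), (33, 47), (128, 96)]:
            for wavelet in ["haar", "db4"]:
                flen = pywt.Wavelet(wavelet).dec_len
                dec = decompose(np.zeros(shape), wavelet, 2)
                h, w = shape
                expected = []
                for _ in range(2):
                    h = (h + flen - 1) // 2
                    w = (w + flen - 1) // 2
                    expected.append((h, w))
                for lvl, triple in enumerate(dec.details):
                    for band in triple:
                        assert band.shape == expected[lvl]
                assert dec.approximation.shape == expected[-1]

    def test_excessive_levels_error_names_maximum(self):
        with pytest.raises(ValueError, match="maximum feasible level"):
            decompose(np.zeros((16, 16)), "db4", levels=6)

    def test_inconsistent_subband_shapes_rejected(self, rng):
        dec = decompose(rng.random((32, 32)), "haar", 1)
        dec.details[0] = (dec.details[0][0][:4, :4],) + dec.details[0][1:]
        with pytest.raises(ValueError, match="inconsistent"):
            reconstruct(dec)


class TestShrinkageFunctions:
    def test_pointwise_examples(self):
        assert shrink(2.0, 1.0, ShrinkageRule("soft")) == pytest.approx(1.0)
        assert shrink(2.0, 1.0, ShrinkageRule("hard")) == pytest.approx(2.0)
        assert shrink(0.5, 1.0, ShrinkageRule("improved", a=0.4)) == pytest.approx(0.2)
        assert shrink(1.0, 1.0, ShrinkageRule("soft")) == 0.0  # tie handled by >= branch

    def test_literal_constant_small_branch(self):
        rule = ShrinkageRule("improved", a=0.4, small_branch="constant")
        assert shrink(0.5, 1.0, rule) == pytest.approx(0.4)

    @settings(derandomize=True, max_examples=200)
    @given(w=finite, lam=lam_st)
    def test_compromise_limits_are_soft_and_hard(self, w, lam):
        assert shrink(w, lam, ShrinkageRule("compromise", a=1.0)) == pytest.approx(
            shrink(w, lam, ShrinkageRule("soft"))
        )
        assert shrink(w, lam, ShrinkageRule("compromise", a=0.0)) == pytest.approx(
            shrink(w, lam, ShrinkageRule("hard"))
        )

    @settings(derandomize=True, max_examples=200)
    @given(w=finite, lam=lam_st)
    def test_improved_zero_a_limit_is_soft(self, w, lam):
        assert shrink(w, lam, ShrinkageRule("improved", a=0.0)) == pytest.approx(
            shrink(w, lam, ShrinkageRule("soft"))
        )

    @settings(derandomize=True, max_examples=200)
    @given(w=finite, lam=lam_st, a=a_st)
    @pytest.mark.parametrize("mode", ["hard", "soft", "compromise", "improved"])
    def test_odd_symmetry(self, mode, w, lam, a):
        rule = ShrinkageRule(mode, a=a)
        assert shrink(-w, lam, rule) == pytest.approx(-shrink(w, lam, rule))

    @settings(derandomize=True, max_examples=200)
    @given(w=finite, lam=lam_st, a=a_st)
    @pytest.mark.parametrize("mode", ["soft", "compromise", "improved"])
    def test_magnitude_never_grows(self, mode, w, lam, a):
        assert abs(shrink(w, lam, ShrinkageRule(mode, a=a))) <= abs(w) + 1e-12

    def test_soft_continuous_at_threshold(self):
        lam = 1.3
        eps = 1e-9
        below = shrink(lam - eps, lam, ShrinkageRule("soft"))
        above = shrink(lam + eps, lam, ShrinkageRule("soft"))
        assert abs(above - below) < 1e-8

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            shrink(1.0, -0.5, ShrinkageRule("soft"))


class TestThresholdSelectors:
    def test_sigma_estimator_definition(self):
        grid = np.array([[0.674, -0.674], [0.674, -0.674]])
        assert estimate_sigma(grid) == pytest.approx(1.0)
        assert estimate_sigma(np.zeros((4, 4))) == 0.0

    def test_sigma_estimator_on_standard_normal_samples(self):
        samples = np.random.default_rng(0).normal(size=(1000, 1000))
        # median(|N(0,1)|) = 0.6745; the 0.674 scaling recovers sigma to <1%.
        assert estimate_sigma(samples) == pytest.approx(1.0, rel=0.01)

    def test_universal_threshold_closed_forms(self):
        assert universal_threshold(0.0, 100) == 0.0
        assert universal_threshold(1.0, 1) == 0.0
        assert universal_threshold(2.0, 1024) == pytest.approx(2 * math.sqrt(2 * math.log(1024)))

    def test_universal_threshold_monotone(self):
        sigmas = [0.1, 0.5, 1.0, 2.0]
        ns = [2, 16, 1024, 10**6]
        vals = [[universal_threshold(s, n) for n in ns] for s in sigmas]
        for row in vals:
            assert row == sorted(row)
        for col in zip(*vals):
            assert list(col) == sorted(col)
        with pytest.raises(ValueError):
            universal_threshold(1.0, 0)

    def test_bayes_threshold_degenerate_branches(self, rng):
        band = rng.normal(size=(64, 64))
        assert bayes_threshold(band, 0.0) == 0.0
        # Mean square exactly sigma^2: no detectable signal, whole band killed.
        sigma = float(np.sqrt(np.mean(band**2)))
        assert bayes_threshold(band, sigma) == pytest.approx(np.max(np.abs(band)))

    def test_bayes_threshold_closed_form_monte_carlo(self):
        # w ~ N(0, sigma_x^2 + sigma^2) with sigma_x=2, sigma=1 -> T = 1/2.
        w = np.random.default_rng(1).normal(scale=np.sqrt(5.0), size=10**6)
        assert bayes_threshold(w, 1.0) == pytest.approx(0.5, rel=0.02)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.empty((0,)))
        with pytest.raises(ValueError):
            bayes_threshold(np.empty((0,)), 1.0)


class TestShrinkDecomposition:
    def test_zero_manual_lambda_is_identity(self, rng):
        img = rng.random((32, 32))
        dec = decompose(img, "db4", 2)
        rule = ShrinkageRule("soft", selector="manual", manual_lambda=0.0)
        out = shrink_decomposition(dec, rule)
        for t_in, t_out in zip(dec.details, out.details):
            for b_in, b_out in zip(t_in, t_out):
                np.testing.assert_allclose(b_out, b_in)
        np.testing.assert_array_equal(out.approximation, dec.approximation)

    def test_huge_threshold_hard_kills_all_details(self, rng):
        img = rng.random((32, 32))
        dec = decompose(img, "db4", 2)
        lam = max(np.max(np.abs(b)) for t in dec.details for b in t) + 1.0
        rule = ShrinkageRule("hard", selector="manual", manual_lambda=lam)
        out = shrink_decomposition(dec, rule)
        for triple in out.details:
            for band in triple:
                assert np.max(np.abs(band)) == 0.0
        # Reconstruction then equals the approximation-only synthesis.
        approx_only = decompose(img, "db4", 2)
        approx_only.details = [tuple(np.zeros_like(b) for b in t) for t in approx_only.details]
        np.testing.assert_allclose(reconstruct(out), reconstruct(approx_only))

    def test_bayes_soft_shrinkage_reduces_noise(self, phantom256):
        from ctdenoise import NoiseSpec, add_gaussian_noise, mse

        rule = ShrinkageRule("soft", selector="bayes")
        ratios = []
        for seed in range(5):
            noisy = add_gaussian_noise(phantom256, NoiseSpec("gaussian", variance=0.04, seed=seed))
            dec = decompose(noisy, "db4", 3)
            rec = np.clip(reconstruct(shrink_decomposition(dec, rule)), 0, 1)
            ratios.append(mse(phantom256, rec) / mse(phantom256, noisy))
        assert np.mean(ratios) < 1.0
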