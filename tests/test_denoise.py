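"""Wavelet shrinkage, bilateral filter and full denoising-chain behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from drdseg.denoise import (
    BilateralParams,
    SubbandPyramid,
    bilateral,
    decompose,
    denoise_image,
    estimate_laplace_scale,
    estimate_sigma_n,
    log_transform,
    inverse_log_transform,
    reconstruct,
    shrink,
    threshold_schedule,
)
from drdseg.metrics import snr_db


class TestLogTransform:
    def test_constant_maps_to_one(self):
        eps = 1e-3
        img = np.full((16, 16), math.e - eps)
        np.testing.assert_allclose(log_transform(img, eps), 1.0)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        back = inverse_log_transform(log_transform(img), 1e-3)
        assert np.abs(back - img).max() < 1e-10

    def test_rejects_negative_intensities(self):
        with pytest.raises(ValueError):
            log_transform(np.array([[0.5, -0.1]]))


class TestDecompose:
    def test_single_level_structure(self):
        pyr = decompose(np.random.default_rng(1).random((84, 84)), "db4", J=1)
        assert pyr.J == 1
        assert set(pyr.levels[0]) == {"lh", "hl", "hh"}
        assert pyr.ll_coarse.ndim == 2
        assert pyr.M_per_subband[0]["hh"] == pyr.levels[0]["hh"].size

    @pytest.mark.parametrize("J", [1, 2, 3])
    def test_perfect_reconstruction(self, J):
        img = np.random.default_rng(2).random((84, 84))
        rec = reconstruct(decompose(img, "db4", J))
        assert np.abs(rec - img).max() < 1e-8

    def test_constant_image_interior_details_vanish(self):
        pyr = decompose(np.full((64, 64), 0.7), "db4", J=1)
        for name in ("lh", "hl", "hh"):
            interior = pyr.levels[0][name][4:-4, 4:-4]  # clear of boundary effects
            assert np.abs(interior).max() < 1e-10

    def test_rejects_too_deep_or_invalid(self):
        img = np.random.default_rng(3).random((16, 16))
        with pytest.raises(ValueError):
            decompose(img, "db4", J=0)
        with pytest.raises(ValueError):
            decompose(img, "db4", J=5)


class TestNoiseEstimate:
    def test_mad_consistency_on_gaussian(self):
        rng = np.random.default_rng(4)
        hh = rng.normal(0.0, 1.0, size=(100, 100))
        pyr = SubbandPyramid(
            levels=[{"lh": hh * 0, "hl": hh * 0, "hh": hh}], ll_coarse=hh * 0, wavelet_name="db4"
        )
        assert abs(estimate_sigma_n(pyr) - 1.0) < 0.05

    def test_zeros_and_hand_computed_median(self):
        z = np.zeros((10, 10))
        pyr = SubbandPyramid(levels=[{"lh": z, "hl": z, "hh": z}], ll_coarse=z, wavelet_name="db4")
        assert estimate_sigma_n(pyr) == 0.0
        patt = np.tile(np.array([-1.0, 0.0, 1.0]), 1000).reshape(50, 60)
        pyr = SubbandPyramid(
            levels=[{"lh": z, "hl": z, "hh": patt}], ll_coarse=z, wavelet_name="db4"
        )
        assert estimate_sigma_n(pyr) == pytest.approx(1.0 / 0.6745)


class TestThresholdSchedule:
    def test_degenerate_cases_are_zero(self):
        assert np.all(threshold_schedule(1.0, 1, 3).T == 0.0)
        assert np.all(threshold_schedule(0.0, 256, 3).T == 0.0)

    def test_closed_form_and_dyadic_ratio(self):
        sched = threshold_schedule(1.0, 256, 3)
        assert sched.T[2] == pytest.approx(2.0 * math.sqrt(2.0 * math.log(256)), rel=1e-12)
        assert sched.T[0] / sched.T[1] == 2.0
        assert sched.T[1] / sched.T[2] == 2.0
        np.testing.assert_array_equal(sched.a, [8.0, 4.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        sigma=st.floats(0.01, 10.0),
        M=st.integers(2, 10**6),
        J=st.integers(1, 6),
    )
    def test_ratio_exactly_two_everywhere(self, sigma, M, J):
        T = threshold_schedule(sigma, M, J).T
        for j in range(J - 1):
            assert T[j] / T[j + 1] == 2.0

    def test_rejects_invalid_m(self):
        with pytest.raises(ValueError):
            threshold_schedule(1.0, 0, 2)


def _shrink_oracle(f: float, T: float, sigma_n: float, s: float) -> float:
    """Independent scalar evaluation of the two-branch gated soft rule."""
    if abs(f) <= T:
        return 0.0
    mag = abs(f) - sigma_n**2 / s
    if mag < 0:
        mag = 0.0
    return mag if f > 0 else -mag


class TestShrink:
    def test_hand_examples(self):
        assert shrink(4.9, 5.0, 1.0, 1.0) == 0.0
        assert shrink(10.0, 5.0, math.sqrt(3.0), 1.0) == pytest.approx(7.0)
        assert shrink(-10.0, 5.0, math.sqrt(3.0), 1.0) == pytest.approx(-7.0)
        assert shrink(5.0, 5.0, 1.0, 1.0) == 0.0  # boundary belongs to the zero branch

    def test_matches_scalar_oracle_on_grid(self):
        fs = np.linspace(-6.0, 6.0, 41)
        Ts = np.linspace(0.0, 4.0, 9)
        sigmas = np.linspace(0.0, 2.0, 9)
        for T in Ts:
            for sigma_n in sigmas:
                got = shrink(fs, T, sigma_n, 1.0)
                want = [_shrink_oracle(f, T, sigma_n, 1.0) for f in fs]
                np.testing.assert_array_equal(got, want)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        f=st.floats(-50, 50),
        T=st.floats(0, 10),
        ratio=st.floats(0, 10),
    )
    def test_odd_nonexpansive_monotone(self, f, T, ratio):
        sn = math.sqrt(ratio)
        g = shrink(f, T, sn, 1.0)
        assert shrink(-f, T, sn, 1.0) == -g
        assert abs(g) <= abs(f) + 1e-12
        bigger = shrink(abs(f) + 1.0, T, sn, 1.0)
        assert bigger >= abs(g)  # monotone in |f| above threshold
        # the pure hard gate (no MAP subtraction) is idempotent
        h = shrink(f, T, 0.0, 1.0)
        assert shrink(h, T, 0.0, 1.0) == h

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            shrink(1.0, 0.5, 1.0, 0.0)


class TestLaplaceScale:
    def test_recovery_with_noise(self):
        rng = np.random.default_rng(5)
        coeffs = rng.laplace(0.0, 1.0, size=10_000) + rng.normal(0.0, 0.5, size=10_000)
        assert estimate_laplace_scale(coeffs, 0.5) == pytest.approx(1.0, abs=0.1)

    def test_recovery_noise_free(self):
        rng = np.random.default_rng(6)
        coeffs = rng.laplace(0.0, 2.0, size=10_000)
        assert estimate_laplace_scale(coeffs, 0.0) == pytest.approx(2.0, abs=0.2)

    def test_pure_noise_clamps_to_floor(self):
        rng = np.random.default_rng(7)
        noise = rng.normal(0.0, 1.0, size=5_000)
        s = estimate_laplace_scale(noise, np.std(noise))
        assert s == pytest.approx(math.sqrt(1e-12 / 2.0))


class TestBilateral:
    def test_constant_fixed_point(self):
        out = bilateral(np.full((20, 20), 0.37), BilateralParams(1.5, 0.05))
        assert np.abs(out - 0.37).max() < 1e-10

    def test_converges_to_gaussian_as_sigma_r_grows(self):
        img = np.random.default_rng(8).random((32, 32))
        params = BilateralParams(sigma_d=1.5, sigma_r=1e9)
        got = bilateral(img, params)
        want = ndimage.gaussian_filter(
            img, sigma=1.5, truncate=params.radius / 1.5, mode="reflect"
        )
        assert np.abs(got - want).max() < 1e-6

    def test_step_edge_preserved(self):
        img = np.zeros((16, 32))
        img[:, 16:] = 1.0
        sharp = bilateral(img, BilateralParams(sigma_d=2.0, sigma_r=0.05))
        row = sharp[8]
        crossing = int(np.argmax(row >= 0.5))
        assert crossing == 16  # half-height crossing unmoved
        blurred = ndimage.gaussian_filter(img, sigma=2.0, mode="reflect")[8]
        assert np.abs(row - img[8]).max() < 0.01
        assert np.abs(blurred - img[8]).max() > 0.1

    def test_rejects_nonpositive_widths(self):
        with pytest.raises(ValueError):
            BilateralParams(sigma_d=0.0, sigma_r=0.1)
        with pytest.raises(ValueError):
            BilateralParams(sigma_d=1.0, sigma_r=-1.0)


class TestDenoiseImage:
    def test_near_identity_on_clean_piecewise_constant(self):
        img = np.full((64, 64), 0.3)
        img[20:40, 20:40] = 0.8
        out = denoise_image(img, bilateral_params=BilateralParams(1.0, 0.05, 2))
        rel = np.abs(out - img).max() / img.max()
        assert rel < 0.02

    def test_speckle_snr_improvement(self, speckle_phantom):
        phantom, noisy = speckle_phantom
        den = denoise_image(noisy)
        assert snr_db(phantom.image, den) >= snr_db(phantom.image, noisy) + 3.0

    def test_disabled_chain_is_identity(self):
        img = np.random.default_rng(9).random((64, 64))
        out = denoise_image(img, sigma_n=0.0, bilateral_params=None)
        assert np.abs(out - img).max() < 1e-8

    def test_shape_preserved_and_nonnegative(self, speckle_phantom):
        _, noisy = speckle_phantom
        out = denoise_image(noisy)
        assert out.shape == noisy.shape
        assert out.min() >= 0.0

    def test_volume_processed_slicewise(self):
        vol = np.random.default_rng(10).random((3, 48, 48))
        out = denoise_image(vol, J=2)
        assert out.shape == vol.shape
        sl = denoise_image(vol[1], J=2)
        np.testing.assert_array_equal(out[1], sl)
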