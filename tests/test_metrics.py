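"""Sharpness index, interface profiles, temporal NMSE, scale fit, PSNR."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noisemapnet.metrics import (BoundaryCurve, ProfileRejected,
                                 evaluate_sharpness, first_pass_window,
                                 generate_interface_profiles, mean_sharpness,
                                 nmse, optimal_scale, psnr, sharpness_index,
                                 temporal_profile)
from noisemapnet.metrics import Profile


def parallel_curves(sep_px=6.0, length_px=10.0, n=5):
    rows = np.linspace(0, length_px, n)
    myo = np.stack([rows, np.full(n, 2.0)], axis=1)
    blood = np.stack([rows, np.full(n, 2.0 + sep_px)], axis=1)
    return BoundaryCurve(myo_points=myo, blood_points=blood)


class TestInterfaceProfiles:
    def test_parallel_lines_on_constant_image(self):
        image = np.full((20, 20), 3.0)
        profiles = generate_interface_profiles(image, parallel_curves(), 1.0)
        assert len(profiles) == 11            # floor(10 mm / 1 mm) + 1
        for p in profiles:
            np.testing.assert_allclose(p.values, 3.0)

    def test_profiles_cross_a_disc_edge(self):
        # disc of value 400 in background 100; profiles span the boundary
        h = w = 64
        rows, cols = np.ogrid[:h, :w]
        image = np.where((rows - 32) ** 2 + (cols - 32) ** 2 <= 12 ** 2, 400.0, 100.0)
        ang = np.linspace(-np.pi / 4, np.pi / 4, 31)
        outer = np.stack([32 + 17 * np.sin(ang), 32 + 17 * np.cos(ang)], axis=1)
        inner = np.stack([32 + 7 * np.sin(ang), 32 + 7 * np.cos(ang)], axis=1)
        curves = BoundaryCurve(myo_points=outer, blood_points=inner)
        for p in generate_interface_profiles(image, curves, 1.0):
            assert p.values[0] < 150 and p.values[-1] > 350

    def test_crossing_curves_rejected(self):
        myo = np.array([[0.0, 0.0], [10.0, 10.0]])
        blood = np.array([[0.0, 10.0], [10.0, 0.0]])
        with pytest.raises(ValueError, match="intersect"):
            BoundaryCurve(myo_points=myo, blood_points=blood)

    def test_zero_length_curve_rejected(self):
        myo = np.array([[5.0, 5.0], [5.0, 5.0]])
        blood = np.array([[0.0, 0.0], [1.0, 0.0]])
        curves = BoundaryCurve(myo_points=myo, blood_points=blood)
        with pytest.raises(ValueError, match="zero-length"):
            generate_interface_profiles(np.zeros((10, 10)), curves)


class TestSharpnessIndex:
    def test_linear_ramp_20_80(self):
        # ramp 0..100 over 5 mm: d = 0.6 * 5 = 3 mm, index = 1/3
        values = np.linspace(0.0, 100.0, 51)
        d, idx = sharpness_index(values, step_mm=0.1)
        assert d == pytest.approx(3.0, abs=1e-9)
        assert idx == pytest.approx(1.0 / 3.0)

    def test_one_sample_step_edge(self):
        # step between adjacent samples at 1 mm spacing: linear interpolation
        # puts the 20% crossing at 0.2 and the 80% at 0.8 -> d = 0.6 mm
        values = np.array([0.0, 0.0, 0.0, 100.0, 100.0])
        d, idx = sharpness_index(values, step_mm=1.0)
        assert d == pytest.approx(0.6)
        assert idx == pytest.approx(1.0 / 0.6)

    def test_amplitude_invariance(self, rng):
        values = np.cumsum(rng.uniform(0, 1, 30))
        d1, _ = sharpness_index(values, 0.5)
        d2, _ = sharpness_index(2.0 * values + 17.0, 0.5)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_flat_and_incomplete_profiles_rejected(self):
        with pytest.raises(ProfileRejected, match="flat"):
            sharpness_index(np.full(10, 5.0), 1.0)
        falling = np.linspace(100.0, 0.0, 10)
        with pytest.raises(ProfileRejected):
            sharpness_index(falling, 1.0)


class TestMeanSharpness:
    def test_mean_of_indices(self):
        profiles = [Profile(np.array([0.0, 50.0, 100.0]), step_mm=1.0 / (2 * 0.5)),
                    Profile(np.array([0.0, 50.0, 100.0]), step_mm=1.0)]
        res = mean_sharpness(profiles)
        # both ramps: d = 0.6 * total width; indices differ by the step
        assert res.n_profiles == 2 and res.n_rejected == 0
        assert res.mean_index_mm1 == pytest.approx(np.mean(res.indices_mm1))

    def test_rejected_profiles_counted_not_averaged(self):
        profiles = [Profile(np.linspace(0, 1, 10), 1.0), Profile(np.full(10, 2.0), 1.0)]
        res = mean_sharpness(profiles)
        assert res.n_rejected == 1
        assert len(res.indices_mm1) == 1

    def test_all_rejected_is_explicit_failure(self):
        with pytest.raises(ValueError, match="all 2 profiles rejected"):
            mean_sharpness([Profile(np.full(5, 1.0), 1.0)] * 2)

    def test_order_invariance(self, rng):
        profs = [Profile(np.sort(rng.uniform(0, 1, 12)), 0.5) for _ in range(6)]
        a = mean_sharpness(profs).mean_index_mm1
        b = mean_sharpness(profs[::-1]).mean_index_mm1
        assert a == pytest.approx(b)


class TestTemporalProfile:
    def test_constant_series(self):
        from noisemapnet.phantom import ImageSeries
        series = ImageSeries(np.full((1, 6, 16, 16), 7.0))
        mask = np.zeros((16, 16), bool)
        mask[4:8, 4:8] = True
        prof = temporal_profile(series, mask, 0, window=(0, 5))
        np.testing.assert_allclose(prof.signal, 7.0)

    def test_phantom_peak_at_analytic_dynamic(self, perfusion_spec):
        from noisemapnet.phantom import (blood_pool_mask,
                                         generate_perfusion_phantom)
        series = generate_perfusion_phantom(perfusion_spec)
        prof = temporal_profile(series, blood_pool_mask(perfusion_spec), 0)
        expected_peak = perfusion_spec.blood_t0 + perfusion_spec.blood_a * \
            perfusion_spec.blood_tau
        assert np.argmax(prof.signal) == int(round(expected_peak))

    def test_single_pixel_roi_is_that_time_course(self, rng):
        from noisemapnet.phantom import ImageSeries
        vox = rng.uniform(1, 10, (1, 8, 16, 16))
        series = ImageSeries(vox)
        mask = np.zeros((16, 16), bool)
        mask[3, 5] = True
        prof = temporal_profile(series, mask, 0, window=(0, 7))
        np.testing.assert_allclose(prof.signal, vox[0, :, 3, 5])

    def test_empty_mask_rejected(self, perfusion_spec):
        from noisemapnet.phantom import generate_perfusion_phantom
        series = generate_perfusion_phantom(perfusion_spec)
        with pytest.raises(ValueError, match="empty"):
            temporal_profile(series, np.zeros((64, 64), bool), 0)


class TestScaleAndNMSE:
    def test_double_amplitude_gives_half_scale(self, rng):
        ref = rng.uniform(1, 5, 20)
        assert optimal_scale(ref, 2.0 * ref) == pytest.approx(0.5)

    def test_orthogonal_signals_give_zero(self):
        assert optimal_scale([1.0, -1.0], [1.0, 1.0]) == pytest.approx(0.0)

    def test_closed_form_matches_grid_search(self, rng):
        for _ in range(20):
            ref = rng.uniform(0, 3, 20)
            tst = rng.uniform(0.5, 3, 20)
            alphas = np.arange(0.0, 5.0, 1e-4)
            errs = ((ref[None, :] - alphas[:, None] * tst[None, :]) ** 2).sum(axis=1)
            brute = alphas[np.argmin(errs)]
            assert optimal_scale(ref, tst) == pytest.approx(brute, abs=1e-3)

    def test_nmse_of_identical_profiles_is_zero(self, rng):
        sig = rng.uniform(0, 10, 15)
        assert nmse(sig, sig).nmse == 0.0

    def test_nmse_small_example(self):
        assert nmse([1.0, 2.0], [1.0, 1.0]).nmse == pytest.approx(0.2)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_scaled_nmse_never_exceeds_unscaled(self, seed):
        r = np.random.default_rng(seed)
        ref = r.normal(2, 1, 12)
        tst = r.normal(2, 1, 12)
        if np.all(tst == 0) or np.sum(ref ** 2) == 0:
            return
        assert nmse(ref, tst, apply_scale=True).nmse <= \
            nmse(ref, tst, apply_scale=False).nmse + 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            optimal_scale([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="zero-energy"):
            nmse([0.0, 0.0], [1.0, 2.0])


class TestPSNR:
    def test_identical_is_infinite(self, rng):
        x = rng.uniform(0, 9, (16, 16))
        assert psnr(x, x) == math.inf

    def test_peak_and_mse_arithmetic(self):
        clean = np.zeros((10, 10))
        clean[0, 0] = 100.0
        test = clean + 1.0
        assert psnr(clean, test) == pytest.approx(40.0)

    def test_more_noise_lowers_psnr(self, rng):
        clean = rng.uniform(0, 100, (32, 32))
        n1 = clean + rng.normal(0, 1, clean.shape)
        n2 = clean + rng.normal(0, 10, clean.shape)
        assert psnr(clean, n1) > psnr(clean, n2)


class TestFirstPassWindow:
    def test_window_brackets_the_bolus(self):
        t = np.arange(40.0)
        from noisemapnet.phantom import gamma_variate
        signal = 60 + 340 * gamma_variate(t, t0=8, a=3, tau=4)
        start, end = first_pass_window(signal)
        assert start <= 20 <= end          # peak at t0 + a*tau = 20
        assert 0 < start < 20
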