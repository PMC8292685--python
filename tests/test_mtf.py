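"""Circular-edge MTF chain: averaging, centring, ESF, LSF, MTF readouts."""

import numpy as np
import pytest
from scipy import stats

from phantomiq import (EdgeSpreadFunction, ImageStack, disk_mtf, esf_to_lsf,
                       estimate_disk_center, generate_stack, lsf_to_mtf,
                       mtf_with_replicates, radial_esf, signal_average)

from conftest import centered_disk_spec, gaussian_f


class TestSignalAverage:
    def test_identical_slices_pass_through(self, small_grid):
        stack = generate_stack(centered_disk_spec(small_grid, 120.0,
                                                  n_slices=4))
        np.testing.assert_allclose(signal_average(stack), stack.data[0])

    def test_symmetric_perturbations_cancel(self):
        scene = np.arange(16.0).reshape(4, 4)
        stack = ImageStack(np.stack([scene + 5.0, scene - 5.0]), 1.0)
        np.testing.assert_allclose(signal_average(stack), scene)

    def test_noise_suppression_follows_averaging_law(self, small_grid):
        spec = centered_disk_spec(small_grid, 0.0, sigma_hu=20.0, seed=61,
                                  n_slices=50)
        avg = signal_average(generate_stack(spec))
        assert avg.std() == pytest.approx(20.0 / np.sqrt(50), rel=0.05)


class TestEstimateDiskCenter:
    @pytest.mark.parametrize("true_center", [(0.0, 0.0), (0.137, -0.291)])
    def test_subpixel_center_recovery(self, small_grid, true_center):
        from phantomiq import DiskInsert, PhantomSpec
        spec = PhantomSpec(grid=small_grid, inserts=(
            DiskInsert(true_center, 12.0, 990.0, "mtf"),))
        img = generate_stack(spec).data[0]
        est = estimate_disk_center(img, (0.5, 0.5), 12.0,
                                   small_grid.pixel_spacing)
        tol = 0.05 * small_grid.pixel_spacing
        assert est[0] == pytest.approx(true_center[0], abs=tol)
        assert est[1] == pytest.approx(true_center[1], abs=tol)

    def test_pure_noise_window_rejected(self, small_grid):
        rng = np.random.default_rng(62)
        img = rng.normal(0.0, 10.0, (128, 128))
        with pytest.raises(ValueError, match="no disk detected"):
            estimate_disk_center(img, (0.0, 0.0), 12.0,
                                 small_grid.pixel_spacing)

    def test_window_exiting_image_rejected(self, small_grid):
        img = np.zeros((128, 128))
        with pytest.raises(ValueError, match="window exits"):
            estimate_disk_center(img, (22.0, 0.0), 12.0,
                                 small_grid.pixel_spacing)


class TestRadialESF:
    def test_sharp_disk_transitions_within_one_pixel(self, small_grid):
        img = generate_stack(centered_disk_spec(small_grid, 990.0)).data[0]
        esf = radial_esf(img, (0.0, 0.0), 6.0, small_grid.pixel_spacing)
        ps = small_grid.pixel_spacing
        inside = esf.radial_positions < -ps
        outside = esf.radial_positions > ps
        np.testing.assert_allclose(esf.values[inside], 990.0, atol=10.0)
        np.testing.assert_allclose(esf.values[outside], 0.0, atol=10.0)

    def test_gaussian_blur_matches_normal_cdf(self, small_grid):
        # for radius >> sigma the edge profile is C * Phi(-pos / sigma)
        sigma = 0.3
        img = generate_stack(centered_disk_spec(small_grid, 990.0,
                                                blur_sigma_mm=sigma)).data[0]
        esf = radial_esf(img, (0.0, 0.0), 6.0, small_grid.pixel_spacing)
        expected = 990.0 * stats.norm.cdf(-esf.radial_positions / sigma)
        assert np.abs(esf.values - expected).max() < 0.012 * 990.0
        at_zero = np.interp(0.0, esf.radial_positions, esf.values)
        assert at_zero == pytest.approx(990.0 / 2.0, rel=0.02)

    def test_annulus_outside_image_rejected(self, small_grid):
        img = np.zeros((128, 128))
        with pytest.raises(ValueError, match="annulus"):
            radial_esf(img, (18.0, 0.0), 6.0, small_grid.pixel_spacing)

    def test_nonuniform_positions_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            EdgeSpreadFunction(np.array([0.0, 0.1, 0.3]), np.zeros(3), 0.1)


class TestEsfToLsf:
    def test_linear_ramp_gives_constant_lsf(self):
        pos = np.arange(-3.0, 3.0, 0.05)
        esf = EdgeSpreadFunction(pos, 4.0 * pos, 0.05)
        np.testing.assert_allclose(esf_to_lsf(esf), 4.0)

    def test_gaussian_cdf_gives_gaussian_lsf_with_matching_sd(self):
        sigma = 0.3
        pos = np.arange(-3.0, 3.0001, 0.02)
        esf = EdgeSpreadFunction(pos, stats.norm.cdf(-pos / sigma), 0.02)
        lsf = esf_to_lsf(esf)
        w = lsf / lsf.sum()
        mu = (w * pos).sum()
        sd = np.sqrt((w * (pos - mu) ** 2).sum())
        assert sd == pytest.approx(sigma, rel=0.02)

    def test_constant_esf_flagged_degenerate(self):
        pos = np.arange(-1.0, 1.0, 0.1)
        esf = EdgeSpreadFunction(pos, np.full(pos.size, 7.0), 0.1)
        with pytest.raises(ValueError, match="degenerate"):
            esf_to_lsf(esf)

    def test_too_few_samples_rejected(self):
        esf = EdgeSpreadFunction(np.arange(3.0) * 0.1, np.arange(3.0), 0.1)
        with pytest.raises(ValueError, match="too few"):
            esf_to_lsf(esf)


class TestLsfToMtf:
    @pytest.mark.parametrize("sigma", [0.2, 0.3, 0.5])
    def test_gaussian_lsf_closed_form_readouts(self, sigma):
        bw = 0.0390625
        pos = np.arange(-3.0, 3.0001, bw)
        lsf = np.exp(-pos ** 2 / (2 * sigma ** 2))
        res = lsf_to_mtf(lsf, bw)
        assert res.f50 == pytest.approx(gaussian_f(0.5, sigma), rel=0.02)
        assert res.f10 == pytest.approx(gaussian_f(0.1, sigma), rel=0.02)
        # curve follows exp(-2 pi^2 s^2 f^2) out to f10
        sel = res.frequencies <= res.f10
        expected = np.exp(-2 * np.pi ** 2 * sigma ** 2 *
                          res.frequencies[sel] ** 2)
        assert np.abs(res.mtf[sel] - expected).max() < 0.02

    def test_impulse_lsf_gives_unity_mtf(self):
        lsf = np.zeros(101)
        lsf[50] = 1.0
        res = lsf_to_mtf(lsf, 0.05, baseline_correct=False, taper=False)
        np.testing.assert_allclose(res.mtf, 1.0, atol=1e-9)
        assert np.isnan(res.f50) and np.isnan(res.f10)

    def test_crossing_interpolation_exact_on_synthetic_curve(self):
        from phantomiq.mtf import _first_crossing
        freqs = np.array([0.0, 0.62, 1.24])
        mtf = np.array([1.0, 0.5 - 1e-12, 0.0])
        assert _first_crossing(freqs, mtf, 0.5) == pytest.approx(0.62,
                                                                 abs=1e-6)

    def test_zero_lsf_rejected(self):
        with pytest.raises(ValueError, match="zero integral"):
            lsf_to_mtf(np.zeros(64), 0.05, baseline_correct=False)


class TestDiskMTFEndToEnd:
    @pytest.mark.parametrize("sigma", [0.2, 0.3, 0.5])
    def test_closed_form_recovery_noiseless(self, small_grid, sigma):
        stack = generate_stack(centered_disk_spec(small_grid, 990.0,
                                                  blur_sigma_mm=sigma))
        res = disk_mtf(stack, (0.4, -0.3), 6.0)
        assert res.f50 == pytest.approx(gaussian_f(0.5, sigma), rel=0.02)
        assert res.f10 == pytest.approx(gaussian_f(0.1, sigma), rel=0.02)
        assert res.f10 > res.f50

    def test_scale_equivariance_doubling_blur_halves_readout(self, small_grid):
        r1 = disk_mtf(generate_stack(centered_disk_spec(
            small_grid, 990.0, blur_sigma_mm=0.2)), (0.0, 0.0), 6.0)
        r2 = disk_mtf(generate_stack(centered_disk_spec(
            small_grid, 990.0, blur_sigma_mm=0.4)), (0.0, 0.0), 6.0)
        assert r2.f50 == pytest.approx(r1.f50 / 2.0, rel=0.02)
        assert r2.f10 == pytest.approx(r1.f10 / 2.0, rel=0.02)

    def test_contrast_invariance(self, small_grid):
        res = {}
        for c in (990.0, 99.0):
            stack = generate_stack(centered_disk_spec(small_grid, c,
                                                      blur_sigma_mm=0.3))
            res[c] = disk_mtf(stack, (0.0, 0.0), 6.0)
        np.testing.assert_allclose(res[990.0].mtf, res[99.0].mtf, atol=1e-6)

    def test_noise_robust_recovery_with_signal_averaging(self, small_grid):
        sigma = 0.3
        spec = centered_disk_spec(small_grid, 990.0, blur_sigma_mm=sigma,
                                  sigma_hu=15.0, seed=63, n_slices=50)
        noiseless = disk_mtf(generate_stack(centered_disk_spec(
            small_grid, 990.0, blur_sigma_mm=sigma)), (0.0, 0.0), 6.0)
        noisy = disk_mtf(generate_stack(spec), (0.0, 0.0), 6.0)
        assert noisy.f50 == pytest.approx(noiseless.f50, rel=0.03)
        assert noisy.f10 > noisy.f50


class TestReplicates:
    def test_identical_replicates_zero_se(self, small_grid):
        stack = generate_stack(centered_disk_spec(small_grid, 990.0,
                                                  blur_sigma_mm=0.3))
        res = mtf_with_replicates([stack] * 10, (0.0, 0.0), 6.0)
        assert res.f50_se == pytest.approx(0.0, abs=1e-12)
        assert res.f10_se == pytest.approx(0.0, abs=1e-12)

    def test_noisy_replicates_mean_near_closed_form(self, small_grid):
        stacks = [generate_stack(centered_disk_spec(
            small_grid, 990.0, blur_sigma_mm=0.3, sigma_hu=10.0,
            seed=700 + i, n_slices=50)) for i in range(10)]
        res = mtf_with_replicates(stacks, (0.0, 0.0), 6.0)
        assert res.f50 == pytest.approx(gaussian_f(0.5, 0.3), rel=0.03)
        assert res.f50_se is not None and res.f50_se < 0.05 * res.f50

    def test_single_replicate_has_no_se(self, small_grid):
        stack = generate_stack(centered_disk_spec(small_grid, 990.0,
                                                  blur_sigma_mm=0.3))
        res = mtf_with_replicates([stack], (0.0, 0.0), 6.0)
        assert res.f50_se is None and res.f10_se is None
        assert res.mtf[0] == pytest.approx(1.0)
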