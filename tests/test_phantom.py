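"""Synthetic phantom generator: rendering, noise calibration, presets."""

import numpy as np
import pytest
import yaml

from phantomiq import (AIR_HU, DiskInsert, GridSpec, NoiseModel, PhantomSpec,
                       catphan_presets, generate_stack,
                       render_noiseless_slice, LOW_CONTRAST_DIAMETERS_MM)

from conftest import centered_disk_spec


class TestGridSpec:
    def test_pixel_spacing_is_fov_over_matrix(self):
        assert GridSpec().pixel_spacing == 400.0 / 1024  # 0.390625 exactly

    @pytest.mark.parametrize("kwargs", [
        {"matrix_size": 32}, {"field_of_view": -1.0}, {"slice_thickness": 0},
    ])
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GridSpec(**kwargs)


class TestRenderNoiseless:
    def test_disk_interior_and_exterior_values(self, small_grid):
        img = render_noiseless_slice(centered_disk_spec(small_grid, 120.0))
        n = small_grid.matrix_size
        assert img[n // 2, n // 2] == pytest.approx(120.0)
        assert img[5, 5] == pytest.approx(0.0)

    @pytest.mark.parametrize("diameter,center", [
        (12.0, (0.0, 0.0)),
        (12.0, (7.3, -4.1)),
        (2.0, (0.0, 0.0)),
        (2.0, (13.37, -7.77)),
    ])
    def test_area_fraction_conserves_integrated_contrast(self, diameter, center):
        # excess HU*area of the rasterized disk vs the analytic pi r^2
        grid = GridSpec()
        spec = PhantomSpec(grid=grid, inserts=(
            DiskInsert(center, diameter, 120.0, "d"),))
        img = render_noiseless_slice(spec)
        excess = img.sum() * grid.pixel_spacing ** 2
        true = 120.0 * np.pi * (diameter / 2.0) ** 2
        assert excess == pytest.approx(true, rel=1e-3)

    def test_empty_scene_is_flat_background(self, small_grid):
        spec = PhantomSpec(grid=small_grid, background_hu=0.0)
        assert not render_noiseless_slice(spec).any()

    def test_air_outside_body(self):
        grid = GridSpec(matrix_size=128, field_of_view=100.0)
        spec = PhantomSpec(grid=grid, background_hu=0.0, body_radius_mm=30.0)
        img = render_noiseless_slice(spec)
        assert img[64, 64] == pytest.approx(0.0)
        assert img[0, 0] == pytest.approx(AIR_HU)

    def test_blur_preserves_integrated_contrast(self, small_grid):
        spec = centered_disk_spec(small_grid, 120.0, blur_sigma_mm=0.5)
        img = render_noiseless_slice(spec)
        excess = img.sum() * small_grid.pixel_spacing ** 2
        assert excess == pytest.approx(120.0 * np.pi * 36.0, rel=1e-3)

    def test_blurred_edge_has_half_amplitude_at_radius(self, small_grid):
        # the Gaussian-blurred edge of a disk crosses ~C/2 at the true edge
        spec = centered_disk_spec(small_grid, 120.0, blur_sigma_mm=0.3)
        img = render_noiseless_slice(spec)
        x = (np.arange(128) - 63.5) * small_grid.pixel_spacing
        row = img[64, :]  # y = -ps/2, essentially through the centre
        v = np.interp(6.0, x, row)
        assert v == pytest.approx(60.0, abs=0.03 * 120.0)

    def test_insert_outside_fov_rejected(self):
        grid = GridSpec(matrix_size=128, field_of_view=50.0)
        with pytest.raises(ValueError, match="aorta"):
            PhantomSpec(grid=grid, inserts=(
                DiskInsert((24.0, 0.0), 12.0, 340.0, "aorta"),))


class TestGenerateStack:
    def test_zero_noise_replicates_noiseless_slice(self, small_grid):
        spec = centered_disk_spec(small_grid, 120.0, n_slices=3)
        stack = generate_stack(spec)
        base = render_noiseless_slice(spec).astype(np.float32)
        assert stack.n_slices == 3
        for sl in stack:
            np.testing.assert_array_equal(sl, base)

    def test_white_noise_sd_calibrated(self, nps_grid):
        # pooled SD over 50 slices of 256^2 samples concentrates within 2%
        spec = PhantomSpec(grid=nps_grid,
                           noise=NoiseModel(sigma_hu=20.0, seed=21),
                           n_slices=50)
        stack = generate_stack(spec)
        assert stack.data.std() == pytest.approx(20.0, rel=0.02)

    @pytest.mark.parametrize("texture,kwargs", [
        ("gaussian_lowpass", {"correlation_length_mm": 0.3}),
        ("target_nps", {"target_nps": (np.linspace(0, 2, 40),
                                       0.2 + np.exp(-np.linspace(0, 2, 40)))}),
    ])
    def test_textured_noise_sd_calibrated(self, nps_grid, texture, kwargs):
        spec = PhantomSpec(grid=nps_grid, n_slices=50,
                           noise=NoiseModel(sigma_hu=12.0, texture=texture,
                                            seed=22, **kwargs))
        stack = generate_stack(spec)
        assert stack.data.std() == pytest.approx(12.0, rel=0.02)

    def test_same_seed_bit_identical(self, small_grid):
        spec = centered_disk_spec(small_grid, 120.0, sigma_hu=15.0, seed=5,
                                  n_slices=4)
        a = generate_stack(spec)
        b = generate_stack(spec)
        assert a.data.tobytes() == b.data.tobytes()

    def test_different_seeds_differ(self, small_grid):
        a = generate_stack(centered_disk_spec(small_grid, 120.0,
                                              sigma_hu=15.0, seed=1))
        b = generate_stack(centered_disk_spec(small_grid, 120.0,
                                              sigma_hu=15.0, seed=2))
        assert not np.array_equal(a.data, b.data)


class TestPresets:
    def test_sensitometry_contrasts(self):
        spec = catphan_presets("sensitometry")
        assert sorted(i.contrast_hu for i in spec.inserts) == [-35.0, 120.0,
                                                               340.0, 990.0]
        assert all(i.diameter == 12.0 for i in spec.inserts)

    def test_low_contrast_ladder(self):
        spec = catphan_presets("low_contrast")
        diam = tuple(i.diameter for i in spec.inserts)
        assert diam == LOW_CONTRAST_DIAMETERS_MM
        assert all(i.contrast_hu == 10.0 for i in spec.inserts)

    def test_low_contrast_convention_configurable(self):
        spec = catphan_presets("low_contrast", hu_per_percent=5.0)
        assert all(i.contrast_hu == 5.0 for i in spec.inserts)

    def test_uniformity_has_no_inserts(self):
        assert catphan_presets("uniformity").inserts == ()

    def test_unknown_module_rejected(self):
        with pytest.raises(ValueError, match="unknown phantom module"):
            catphan_presets("resolution")


class TestSerialization:
    def test_yaml_round_trip(self, small_grid):
        spec = centered_disk_spec(small_grid, 340.0, blur_sigma_mm=0.2,
                                  sigma_hu=10.0, seed=3, n_slices=7)
        again = PhantomSpec.from_yaml(spec.to_yaml())
        assert again == spec

    def test_yaml_round_trip_with_target_nps(self, small_grid):
        f = np.linspace(0, 1.0, 16)
        spec = PhantomSpec(grid=small_grid, n_slices=2,
                           noise=NoiseModel(sigma_hu=4.0, texture="target_nps",
                                            target_nps=(f, 1.0 + f), seed=9))
        again = PhantomSpec.from_yaml(spec.to_yaml())
        np.testing.assert_allclose(again.noise.target_nps[1], 1.0 + f)
        a = generate_stack(spec)
        b = generate_stack(again)
        assert a.data.tobytes() == b.data.tobytes()

    def test_invalid_noise_model(self):
        with pytest.raises(ValueError):
            NoiseModel(sigma_hu=-1.0)
        with pytest.raises(ValueError):
            NoiseModel(sigma_hu=1.0, texture="pink")
        with pytest.raises(ValueError):
            NoiseModel(sigma_hu=1.0, texture="gaussian_lowpass")
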