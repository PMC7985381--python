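"""Phantom generation and projection acquisition."""

import numpy as np
import pytest
from skimage.transform import radon

from optmorph.simulate import (PhantomSpec, PlacementError, ProjectionStack,
                               add_noise, apply_illumination_field,
                               attenuation_to_transmission, default_angles,
                               forward_project, generate_phantom)


class TestPhantomGeneration:
    def test_empty_phantom(self):
        spec = PhantomSpec(volume_shape_voxels=(16, 16, 16), n_cells=0,
                           tube_inner_diameter_um=70.0)
        vol, truth = generate_phantom(spec)
        assert not np.any(vol)
        assert truth.n_cells == 0

    def test_density_to_count_arithmetic(self):
        # cylinder sized to exactly 1.0 µL: r = 564.19 µm, h = 1000 µm
        r_um = np.sqrt(1e9 / (np.pi * 1000.0))
        spec = PhantomSpec(
            volume_shape_voxels=(100, 120, 120),
            voxel_pitch_um=10.0,
            tube_inner_diameter_um=2 * r_um,
            seeded_density_cells_per_ml=300_000.0,
            semi_axis_range_um=(5.0, 10.0),
        )
        assert spec.resolve_n_cells() == 300

    def test_inconsistent_count_and_density_rejected(self):
        spec = PhantomSpec(volume_shape_voxels=(64, 64, 64),
                           tube_inner_diameter_um=280.0,
                           n_cells=500, seeded_density_cells_per_ml=300_000.0)
        with pytest.raises(ValueError, match="inconsistent"):
            spec.resolve_n_cells()

    def test_determinism_under_fixed_seed(self):
        spec = PhantomSpec(volume_shape_voxels=(48, 48, 48),
                           tube_inner_diameter_um=200.0, n_cells=20,
                           semi_axis_range_um=(5.0, 20.0), rng_seed=42)
        v1, t1 = generate_phantom(spec)
        v2, t2 = generate_phantom(spec)
        assert np.array_equal(v1, v2)
        assert t1.cells.equals(t2.cells)

    def test_cells_inside_tube(self, small_spec, small_phantom):
        _, truth = small_phantom
        nyx = small_spec.volume_shape_voxels[1]
        center = (nyx // 2) * small_spec.voxel_pitch_um
        r = np.hypot(truth.cells.center_y_um - center,
                     truth.cells.center_x_um - center)
        assert np.all(r + truth.cells.a_um <= small_spec.tube_radius_um + 1e-9)

    def test_truth_registry_consistency(self, small_phantom):
        _, truth = small_phantom
        c = truth.cells
        assert (c.a_um >= c.b_um).all() and (c.b_um >= c.c_um).all()
        assert (c.c_um > 0).all()
        assert truth.realized_density_cells_per_ml == pytest.approx(
            truth.n_cells / truth.analysis_cylinder_volume_ml)

    def test_dead_cell_contrast_exact(self):
        spec = PhantomSpec(volume_shape_voxels=(48, 48, 48),
                           tube_inner_diameter_um=200.0, n_cells=12,
                           semi_axis_range_um=(6.0, 10.0),
                           cell_contrast=2.0, dead_fraction=0.5,
                           dead_contrast_factor=0.25, rng_seed=9)
        vol, truth = generate_phantom(spec)
        assert truth.n_dead == 6  # exact rounded fraction
        values = set(np.unique(vol))
        assert values == {0.0, 0.5, 2.0}  # dead = factor x live exactly

    def test_placement_failure_raises(self):
        spec = PhantomSpec(volume_shape_voxels=(32, 32, 32),
                           tube_inner_diameter_um=140.0, n_cells=200,
                           semi_axis_range_um=(12.0, 15.0),
                           max_retries_per_cell=20)
        with pytest.raises(PlacementError):
            generate_phantom(spec)


class TestForwardProjection:
    def test_default_acquisition_is_400_angles(self):
        angles = default_angles()
        assert len(angles) == 400
        assert np.allclose(np.diff(angles), 0.9)

    def test_zero_volume_projects_to_zero(self):
        stack = forward_project(np.zeros((8, 16, 16)), default_angles(10))
        assert not np.any(stack.data)

    def test_impulse_on_axis_is_constant_column(self):
        vol = np.zeros((4, 33, 33))
        vol[2, 16, 16] = 1.0  # n // 2: the rotation axis pixel
        stack = forward_project(vol, default_angles(36))
        cols = np.argmax(stack.data[:, 2, :], axis=1)
        assert np.all(cols == 16)

    def test_off_axis_impulse_sinusoid_amplitude(self):
        vol = np.zeros((3, 64, 64))
        rho = 20
        vol[1, 32, 32 + rho] = 1.0
        stack = forward_project(vol, default_angles(90))
        cols = np.argmax(stack.data[:, 1, :], axis=1)
        amplitude = np.abs(cols - 32).max()
        assert abs(amplitude - rho) <= 1

    def test_matches_independent_rotate_and_sum_oracle(self, rng):
        """Slice projections agree with skimage's radon transform."""
        n = 32
        yy, xx = np.mgrid[0:n, 0:n]
        mask = (yy - (n - 1) / 2) ** 2 + (xx - (n - 1) / 2) ** 2 <= (n / 2 - 3) ** 2
        img = rng.random((n, n)) * mask
        angles = np.linspace(0.0, 360.0, 24, endpoint=False)
        stack = forward_project(img[None, :, :], angles)
        oracle = radon(img, theta=angles, circle=True).T
        assert np.allclose(stack.data[:, 0, :], oracle, atol=1e-8)

    def test_linearity(self, rng):
        n = 24
        yy, xx = np.mgrid[0:n, 0:n]
        mask = (yy - (n - 1) / 2) ** 2 + (xx - (n - 1) / 2) ** 2 <= (n / 2 - 3) ** 2
        v1 = rng.random((4, n, n)) * mask
        v2 = rng.random((4, n, n)) * mask
        angles = np.linspace(0.0, 360.0, 12, endpoint=False)
        lhs = forward_project(2.0 * v1 + 3.0 * v2, angles).data
        rhs = 2.0 * forward_project(v1, angles).data + 3.0 * forward_project(v2, angles).data
        assert np.allclose(lhs, rhs, atol=1e-6)

    def test_mass_conservation_per_angle(self, small_phantom, small_stack):
        vol, _ = small_phantom
        slice_sums = vol.sum(axis=(1, 2))
        proj_sums = small_stack.data.sum(axis=2)  # (angle, z)
        scale = max(slice_sums.max(), 1.0)
        assert np.allclose(proj_sums, slice_sums[None, :], atol=0.02 * scale)

    def test_cor_offset_shifts_detector_columns(self):
        vol = np.zeros((3, 64, 64))
        vol[1, 32, 45] = 1.0
        angles = default_angles(12)
        base = forward_project(vol, angles).data
        shifted = forward_project(vol, angles, cor_offset_px=4.0).data
        assert np.allclose(shifted[:, :, 4:], base[:, :, :-4], atol=1e-9)

    def test_rejects_bad_angles(self):
        vol = np.zeros((4, 8, 8))
        with pytest.raises(ValueError):
            forward_project(vol, np.array([]))
        with pytest.raises(ValueError):
            forward_project(vol, np.array([10.0, 5.0]))
        with pytest.raises(ValueError):
            forward_project(vol, np.array([0.0, 360.0]))

    def test_rejects_non_finite_volume(self):
        vol = np.full((4, 8, 8), np.nan)
        with pytest.raises(ValueError, match="finite"):
            forward_project(vol, default_angles(4))


class TestIlluminationAndNoise:
    def _flat_stack(self, value=1.0, n=32):
        return ProjectionStack(np.full((6, n, n), value),
                               default_angles(6), 5.0)

    def test_zero_amplitude_is_identity(self):
        stack = self._flat_stack()
        out = apply_illumination_field(stack, 0.0, rng_seed=1)
        assert np.array_equal(out.data, stack.data)

    def test_field_bounds(self):
        out = apply_illumination_field(self._flat_stack(), 0.5, rng_seed=2)
        assert out.data.min() >= 0.5 - 1e-12
        assert out.data.max() <= 1.5 + 1e-12

    def test_field_reproducible_and_low_frequency(self):
        a = apply_illumination_field(self._flat_stack(), 0.3, rng_seed=7)
        b = apply_illumination_field(self._flat_stack(), 0.3, rng_seed=7)
        assert np.array_equal(a.data, b.data)
        g = a.data[0] - 1.0
        assert abs(g.mean()) < 1e-12  # zero-mean harmonics

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            apply_illumination_field(self._flat_stack(), -0.1)

    def test_noise_zero_scale_identity(self):
        stack = self._flat_stack(100.0)
        out = add_noise(stack, 0.0, rng_seed=1)
        assert np.array_equal(out.data, stack.data)

    def test_noise_unbiased(self):
        stack = self._flat_stack(100.0, n=128)
        out = add_noise(stack, 0.5, rng_seed=11)
        assert out.data.min() >= 0
        assert out.data.mean() == pytest.approx(100.0, rel=0.01)

    def test_negative_noise_scale_rejected(self):
        with pytest.raises(ValueError):
            add_noise(self._flat_stack(), -1.0)

    def test_transmission_layer_positive_and_monotone(self, small_stack):
        trans = attenuation_to_transmission(small_stack, i0=2.0)
        assert trans.data.max() <= 2.0 + 1e-12
        assert trans.data.min() > 0
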