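"""Equivalent-ellipsoid shape descriptors, density and viability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from optmorph.morphometry import (cell_density, cell_table, cylinder_volume_ml,
                                  density_fraction, elongation,
                                  fit_ellipsoid_radii, flatness,
                                  summarize_sample, viability)
from optmorph.segment import LabelVolume, label_components


def digitized_ellipsoid_coords(semi_axes_vox, rot=None):
    """Voxel centers inside an (optionally rotated) ellipsoid at the origin."""
    a = max(semi_axes_vox)
    n = int(np.ceil(2 * a)) + 4
    c = n / 2.0
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    pts = np.stack([zz - c, yy - c, xx - c], axis=-1)
    if rot is not None:
        pts = pts @ rot.as_matrix()
    inside = np.sum((pts / np.asarray(semi_axes_vox)) ** 2, axis=-1) <= 1.0
    return np.argwhere(inside)


class TestEllipsoidRadii:
    def test_digitized_sphere_radius_recovered(self):
        coords = digitized_ellipsoid_coords((10, 10, 10))  # 20 µm at 2 µm pitch
        (r1, r2, r3), valid = fit_ellipsoid_radii(coords, 2.0)
        assert valid
        for r in (r1, r2, r3):
            assert r == pytest.approx(20.0, abs=1.0)

    def test_axis_aligned_ellipsoid(self):
        coords = digitized_ellipsoid_coords((20, 10, 5))  # (40, 20, 10) µm at 2 µm
        (r1, r2, r3), valid = fit_ellipsoid_radii(coords, 2.0)
        assert valid
        assert r1 == pytest.approx(40.0, rel=0.10)
        assert r2 == pytest.approx(20.0, rel=0.10)
        assert r3 == pytest.approx(10.0, rel=0.10)

    def test_single_voxel_invalid(self):
        (_, _, r3), valid = fit_ellipsoid_radii(np.array([[3, 3, 3]]), 2.0)
        assert not valid
        assert r3 >= 1.0  # floored at pitch/2

    def test_coplanar_voxels_invalid(self):
        zz, yy = np.mgrid[0:10, 0:10]
        coords = np.stack([zz.ravel(), yy.ravel(), np.zeros(100)], axis=1)
        (_, _, r3), valid = fit_ellipsoid_radii(coords, 2.0)
        assert not valid
        assert r3 >= 1.0

    def test_rotation_robustness(self):
        rng = np.random.default_rng(5)
        values = []
        for _ in range(10):
            rot = Rotation.random(rng=rng)
            coords = digitized_ellipsoid_coords((16, 8, 8), rot)
            (r1, r2, _), _ = fit_ellipsoid_radii(coords, 1.0)
            values.append(elongation(r1, r2))
        assert np.ptp(values) / np.mean(values) < 0.10

    def test_sphere_limit_monotone(self):
        """elongation -> 1 from above as the sphere gets better resolved."""
        errs = []
        for r in (5, 10, 20):
            coords = digitized_ellipsoid_coords((r, r, r))
            (r1, r2, _), _ = fit_ellipsoid_radii(coords, 1.0)
            errs.append(abs(elongation(r1, r2) - 1.0))
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[2] < 0.01


class TestShapeIndices:
    @pytest.mark.parametrize("radii,expected", [
        ((20.0, 20.0), 1.0), ((40.0, 20.0), 2.0), ((30.0, 12.0), 2.5)])
    def test_elongation_arithmetic(self, radii, expected):
        assert elongation(*radii) == pytest.approx(expected)

    @pytest.mark.parametrize("radii,expected", [
        ((20.0, 20.0), 1.0), ((20.0, 10.0), 2.0), ((12.0, 4.0), 3.0)])
    def test_flatness_arithmetic(self, radii, expected):
        assert flatness(*radii) == pytest.approx(expected)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            elongation(10.0, 0.0)
        with pytest.raises(ValueError):
            flatness(10.0, -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(r1=st.floats(1.0, 100.0), r2=st.floats(1.0, 100.0),
           r3=st.floats(1.0, 100.0), scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, r1, r2, r3, scale):
        a, b, c = sorted((r1, r2, r3), reverse=True)
        assert elongation(a * scale, b * scale) == pytest.approx(elongation(a, b))
        assert flatness(b * scale, c * scale) == pytest.approx(flatness(b, c))
        assert elongation(a, b) >= 1.0 and flatness(b, c) >= 1.0


class TestDensityAndViability:
    def test_density_arithmetic(self):
        assert cell_density(300, 0.001) == pytest.approx(300_000.0)
        assert cell_density(0, 0.5) == 0.0
        with pytest.raises(ValueError):
            cell_density(1, 0.0)

    def test_quantified_vs_initial_fractions(self):
        assert density_fraction(169_007, 300_000) == 56
        assert density_fraction(307_518, 500_000) == 62
        assert density_fraction(563_262, 1_000_000) == 56
        assert density_fraction(12345.0, 12345.0) == 100

    def test_viability_arithmetic(self):
        assert viability(9, 5) == 64.3
        assert viability(10, 0) == 100.0
        with pytest.raises(ValueError):
            viability(0, 0)

    def test_cylinder_volume(self):
        # r = 564.19 µm, h = 1000 µm -> 1.0 µL
        r = np.sqrt(1e9 / (np.pi * 1000.0))
        assert cylinder_volume_ml(r, 1000.0) == pytest.approx(1e-3)


class TestSummaries:
    def _two_shape_labels(self):
        labels = np.zeros((40, 40, 40), dtype=np.int32)
        zz, yy, xx = np.mgrid[0:40, 0:40, 0:40]
        sphere = ((zz - 10.0) ** 2 + (yy - 10.0) ** 2 + (xx - 10.0) ** 2) <= 36.0
        rod = (((zz - 28.0) / 10.0) ** 2 + ((yy - 28.0) / 4.0) ** 2
               + ((xx - 28.0) / 4.0) ** 2) <= 1.0
        labels[sphere] = 1
        labels[rod] = 2
        return LabelVolume(labels, 2, voxel_pitch_um=2.0)

    def test_empty_label_volume(self):
        lv = LabelVolume(np.zeros((4, 4, 4), np.int32), 0, 5.0)
        metrics, table = summarize_sample(lv)
        assert metrics.n_cells == 0
        assert len(table) == 0

    def test_constructed_shapes_measured(self):
        metrics, table = summarize_sample(self._two_shape_labels())
        assert metrics.n_cells == 2
        sphere = table[table.label_id == 1].iloc[0]
        rod = table[table.label_id == 2].iloc[0]
        assert sphere.R_largest_um == pytest.approx(12.0, rel=0.12)
        assert sphere.elongation == pytest.approx(1.0, abs=0.05)
        assert rod.elongation == pytest.approx(2.5, rel=0.10)
        assert rod.R_smallest_um == pytest.approx(8.0, rel=0.12)

    def test_tables_byte_identical_across_runs(self, tmp_path):
        lv = self._two_shape_labels()
        paths = []
        for name in ("a.csv", "b.csv"):
            _, table = summarize_sample(lv)
            p = tmp_path / name
            table.to_csv(p, index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_quartiles_use_linear_interpolation(self):
        lv = self._two_shape_labels()
        metrics, table = summarize_sample(lv)
        vals = np.sort(table.elongation.to_numpy())
        assert metrics.elongation_median == pytest.approx(np.mean(vals))

    def test_density_from_label_volume(self):
        lv = self._two_shape_labels()
        metrics, _ = summarize_sample(lv, analysis_volume_ml=1e-6)
        assert metrics.density_cells_per_ml == pytest.approx(2e6)
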