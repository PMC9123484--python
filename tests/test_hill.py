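"""Hill-of-vision engine: interpolation fidelity, solid angles, volumes."""

import numpy as np
import pytest
from scipy.integrate import quad

from perifield.grid import Eye, Subfield, build_grid
from perifield.hill import (
    InterpolationError,
    cap_fraction,
    cap_solid_angle,
    composite_map,
    hill_of_vision,
    interpolate_field,
    interpolate_points,
    solid_angle_weights,
    subfield_fractions,
    volume,
)


@pytest.fixture(scope="module")
def example_exam(small_cohort):
    exams, _ = small_cohort
    return exams[0]


class TestInterpolation:
    def test_node_values_reproduced(self, od_grid, example_exam):
        raster = interpolate_field(example_exam, od_grid)
        at_nodes = raster(od_grid.x, od_grid.y)
        assert np.nanmax(np.abs(at_nodes - example_exam.sensitivities)) < 1e-6

    def test_affine_surface_reproduced_everywhere(self, od_grid):
        v = 30 + 0.1 * od_grid.x - 0.2 * od_grid.y  # positive over the grid
        raster = interpolate_field(v, od_grid)
        gx, gy = raster.grid_xy
        expected = 30 + 0.1 * gx - 0.2 * gy
        err = np.abs(raster.values - expected)
        assert np.nanmax(err) < 1e-6

    def test_no_extrapolation_outside_hull(self, od_grid):
        raster = interpolate_field(np.full(185, 10.0), od_grid)
        assert np.isnan(raster(100.0, 100.0))
        assert not np.all(raster.defined)  # lattice corners fall outside the hull

    def test_collinear_points_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(InterpolationError):
            interpolate_points(x, 2 * x, np.ones(5))

    def test_invalid_resolution_rejected(self, od_grid):
        with pytest.raises(ValueError):
            interpolate_field(np.zeros(185), od_grid, resolution_deg=0.0)


class TestSolidAngles:
    def test_full_sphere_partition(self):
        # a disc of planar radius 180 deg covers the whole sphere
        xx, yy = np.meshgrid(np.linspace(-180, 180, 80), np.linspace(-180, 180, 80))
        m = np.hypot(xx, yy) <= 180
        raster = interpolate_points(xx[m], yy[m], np.ones(m.sum()), resolution_deg=1.0)
        total = volume(raster, cap_fraction(raster, 180.0), solid_angle_weights(raster))
        assert total == pytest.approx(4 * np.pi, rel=1e-3)

    def test_30_degree_cap(self, od_grid):
        raster = interpolate_field(np.full(185, 1.0), od_grid)
        w = solid_angle_weights(raster)
        cap = volume(raster, cap_fraction(raster, 30.0), w)
        assert cap == pytest.approx(cap_solid_angle(30.0), rel=1e-4)
        assert cap_solid_angle(30.0) == pytest.approx(0.8418, abs=5e-4)

    def test_quadrature_convergence_on_halved_resolution(self, od_grid, example_exam):
        r1 = interpolate_field(example_exam, od_grid, 0.5)
        r2 = interpolate_field(example_exam, od_grid, 0.25)
        w1 = float((solid_angle_weights(r1) * r1.defined).sum())
        w2 = float((solid_angle_weights(r2) * r2.defined).sum())
        assert abs(w1 / w2 - 1) < 1e-3


class TestVolume:
    def test_uniform_cap_volume(self, od_grid):
        raster = interpolate_field(np.full(185, 10.0), od_grid)
        v = volume(raster, cap_fraction(raster, 30.0))
        assert v == pytest.approx(10 * cap_solid_angle(30.0), rel=0.005)

    def test_linearity_in_sensitivity(self, od_grid, example_exam):
        r1 = interpolate_field(example_exam.sensitivities, od_grid)
        r2 = interpolate_field(2.0 * example_exam.sensitivities, od_grid)
        assert volume(r2) == pytest.approx(2.0 * volume(r1), rel=1e-9)

    def test_cone_profile_against_quadrature_oracle(self):
        R, s0 = 40.0, 20.0
        angles = np.deg2rad(np.arange(0, 360, 5))
        pts = [(0.0, 0.0)]
        for ecc in np.arange(2.0, R + 0.1, 2.0):
            pts.extend((ecc * np.cos(a), ecc * np.sin(a)) for a in angles)
        pts = np.asarray(pts)
        ecc = np.hypot(pts[:, 0], pts[:, 1])
        raster = interpolate_points(pts[:, 0], pts[:, 1], s0 * (1 - ecc / R))
        v = volume(raster, cap_fraction(raster, R))
        oracle = 2 * np.pi * s0 * quad(
            lambda t: (1 - np.degrees(t) / R) * np.sin(t), 0, np.deg2rad(R)
        )[0]
        assert v == pytest.approx(oracle, rel=0.005)

    def test_empty_region_rejected(self, od_grid):
        raster = interpolate_field(np.full(185, 1.0), od_grid)
        with pytest.raises(ValueError, match="empty region"):
            volume(raster, np.zeros_like(raster.values))

    def test_sanity_bracket(self, od_grid, example_exam):
        hov = hill_of_vision(example_exam, od_grid)
        hull = float((hov.cell_solid_angle * hov.raster.defined).sum())
        s = example_exam.sensitivities
        assert s.min() * hull - 1e-9 <= hov.v_tot <= s.max() * hull + 1e-9


class TestHillOfVision:
    def test_subfield_volumes_sum_to_total(self, od_grid, example_exam):
        hov = hill_of_vision(example_exam, od_grid)
        assert sum(hov.v_subfield.values()) == pytest.approx(hov.v_tot, rel=1e-6)
        assert hov.v_30 == hov.v_subfield[Subfield.CENTRAL30]

    def test_volume_invariant_under_mirroring(self, od_grid, os_grid, example_exam):
        # same pointwise data fed to the OD grid and its OS mirror
        h_od = hill_of_vision(example_exam.sensitivities, od_grid)
        h_os = hill_of_vision(example_exam.sensitivities, os_grid)
        assert h_os.v_tot == pytest.approx(h_od.v_tot, rel=1e-9)
        for sf in Subfield:
            assert h_os.v_subfield[sf] == pytest.approx(h_od.v_subfield[sf], rel=1e-6)

    def test_subfield_fractions_partition_each_cell(self, od_grid):
        raster = interpolate_field(np.zeros(185), od_grid)
        fr = subfield_fractions(raster, Eye.OD)
        total = sum(fr.values())
        assert np.allclose(total, 1.0)

    def test_raster_values_non_negative(self, od_grid, example_exam):
        hov = hill_of_vision(example_exam, od_grid)
        vals = hov.raster.values[hov.raster.defined]
        assert np.all(vals >= -1e-9)


class TestCompositeMap:
    def test_single_exam_equals_own_raster(self, od_grid, example_exam):
        comp = composite_map([example_exam], od_grid)
        own = interpolate_field(example_exam, od_grid)
        assert np.allclose(comp.values, own.values, equal_nan=True)

    def test_two_constant_fields_average(self, od_grid):
        comp = composite_map({"a": np.full(185, 4.0), "b": np.full(185, 6.0)}, od_grid)
        assert np.nanmax(np.abs(comp.values - 5.0)) < 1e-9

    def test_mixed_lateralities_rejected(self, od_grid, small_cohort):
        exams, _ = small_cohort
        mixed = [exams[0], next(e for e in exams if e.eye is Eye.OS)]
        with pytest.raises(ValueError, match="laterality"):
            composite_map(mixed, od_grid)

    def test_cohort_peak_lies_in_central_or_inferotemporal(self, od_grid, small_cohort):
        from perifield.agreement import select_reference_test
        from perifield.grid import classify_subfield

        exams, _ = small_cohort
        by = {}
        for e in exams:
            if e.eye is Eye.OD:
                by.setdefault(e.subject_id, []).append(e)
        refs = [select_reference_test(v) for v in by.values()]
        comp = composite_map([r for r in refs if r is not None], od_grid)
        j, i = np.unravel_index(np.nanargmax(comp.values), comp.values.shape)
        x, y = comp.xs[i], comp.ys[j]
        sf = classify_subfield(x, y, np.hypot(x, y))  # OD: temporal_x = x
        assert sf in (Subfield.CENTRAL30, Subfield.INFEROTEMPORAL)
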