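"""Timepoint presets, profile construction, boundary-layer meshing, y+."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from portaflow import geometry as geo
from portaflow.geometry import (BoundaryLayerSpec, boundary_layer_total_thickness,
                                build_axisymmetric_profile, build_mesh,
                                estimate_yplus, make_timepoint_spec)

MM = 1e-3


class TestPresets:
    @pytest.mark.parametrize("label,throat,pre,peak", [
        ("preop", 5.1, 15.2, 13.45),
        ("week1", 8.0, 12.0, 13.32),
        ("month6", 8.0, 11.0, 15.13),
    ])
    def test_printed_dimensions(self, label, throat, pre, peak):
        spec = make_timepoint_spec(label)
        assert spec.throat_diameter == pytest.approx(throat * MM)
        assert spec.prestenotic_max_diameter == pytest.approx(pre * MM)
        assert spec.inlet_peak_velocity == pytest.approx(peak / 100.0)
        assert spec.branch_diameters == (5.0 * MM, 7.3 * MM)

    def test_unknown_label_lists_valid_labels(self):
        with pytest.raises(ValueError, match="preop.*week1.*month6"):
            make_timepoint_spec("month12")

    def test_area_contraction_ratio_preop(self):
        spec = make_timepoint_spec("preop")
        assert spec.area_contraction_ratio == pytest.approx((15.2 / 5.1) ** 2, rel=1e-12)
        assert spec.area_contraction_ratio == pytest.approx(8.88, abs=0.01)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_timepoint_spec("preop").__class__(
                label="bad", inlet_diameter=0.01, prestenotic_max_diameter=0.01,
                throat_diameter=0.012, stenosis_length=0.01,
                downstream_trunk_diameter=0.012, branch_diameters=(0.005, 0.007),
                branch_lengths=(0.03, 0.03), inlet_peak_velocity=0.1)


class TestProfile:
    def test_preop_min_radius_is_half_throat(self):
        prof = build_axisymmetric_profile(make_timepoint_spec("preop"))
        assert prof.r.min() == pytest.approx(2.55 * MM, rel=1e-3)

    def test_attains_prestenotic_and_trunk_radii(self):
        spec = make_timepoint_spec("preop")
        prof = build_axisymmetric_profile(spec)
        assert prof.r.max() == pytest.approx(spec.prestenotic_max_diameter / 2, rel=1e-12)
        assert prof.radius(spec.total_length) == pytest.approx(
            spec.downstream_trunk_diameter / 2, rel=1e-12)

    def test_degenerate_spec_gives_straight_tube(self, tube_case):
        prof = build_axisymmetric_profile(tube_case.spec(), 100)
        assert np.allclose(prof.r, tube_case.radius)

    def test_c1_continuity(self):
        # secant-slope jumps scale with the sampling step for a C1 radius
        # function (a slope kink would leave them constant under refinement)
        prof = build_axisymmetric_profile(make_timepoint_spec("preop"))
        jumps = []
        for n in (6001, 12001):
            z = np.linspace(0.0, prof.length, n)
            slope = np.diff(prof.radius(z)) / np.diff(z)
            jumps.append(np.max(np.abs(np.diff(slope))))
        assert jumps[1] == pytest.approx(jumps[0] / 2.0, rel=0.1)

    def test_area_amplification_at_least_one(self):
        for label in geo.TIMEPOINT_LABELS:
            prof = build_axisymmetric_profile(make_timepoint_spec(label))
            assert prof.area_amplification >= 1.0

    def test_samples_strictly_increasing(self):
        prof = build_axisymmetric_profile(make_timepoint_spec("week1"))
        assert np.all(np.diff(prof.z) > 0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            build_axisymmetric_profile(make_timepoint_spec("preop"), 10)


class TestBoundaryLayer:
    def test_printed_parameters_total_thickness(self):
        bl = BoundaryLayerSpec(0.065 * MM, 1.2, 5)
        expect = 0.065 * MM * (1.2**5 - 1.0) / 0.2
        assert boundary_layer_total_thickness(bl) == pytest.approx(expect, rel=1e-12)
        assert boundary_layer_total_thickness(bl) == pytest.approx(0.4837 * MM, rel=1e-3)

    def test_single_layer_identity(self):
        assert boundary_layer_total_thickness(
            BoundaryLayerSpec(1e-4, 1.7, 1)) == pytest.approx(1e-4)

    def test_unit_growth_arithmetic_sum(self):
        assert boundary_layer_total_thickness(
            BoundaryLayerSpec(0.065 * MM, 1.0, 5)) == pytest.approx(0.325 * MM)

    @settings(derandomize=True, max_examples=50)
    @given(h=st.floats(1e-6, 1e-3), g=st.floats(1.0, 2.0), n=st.integers(1, 12))
    def test_closed_form_matches_height_sum(self, h, g, n):
        bl = BoundaryLayerSpec(h, g, n)
        assert boundary_layer_total_thickness(bl) == pytest.approx(
            float(np.sum(bl.heights)), rel=1e-9)

    def test_invalid_specs_rejected(self):
        for kw in (dict(first_layer_height=0.0), dict(growth_rate=0.9),
                   dict(n_layers=0)):
            with pytest.raises(ValueError):
                BoundaryLayerSpec(**{**dict(first_layer_height=1e-4,
                                            growth_rate=1.2, n_layers=5), **kw})


class TestMesh:
    def test_wall_layer_heights_follow_progression(self):
        prof = build_axisymmetric_profile(make_timepoint_spec("preop"))
        bl = BoundaryLayerSpec()
        mesh = build_mesh(prof, 0.65 * MM, bl)
        heights = mesh.wall_layer_heights()          # (stations, n_layers)
        expect = bl.heights
        rel = np.abs(heights - expect[None, :]) / expect[None, :]
        assert rel.max() < 0.05

    def test_refinement_monotonicity(self):
        prof = build_axisymmetric_profile(make_timepoint_spec("preop"))
        coarse = build_mesh(prof, 1.0 * MM)
        fine = build_mesh(prof, 0.5 * MM)
        assert fine.n_cells > coarse.n_cells
        assert len(fine.nodes) > len(coarse.nodes)

    def test_straight_tube_volume_matches_cylinder(self, tube_case):
        prof = build_axisymmetric_profile(tube_case.spec(), 100)
        mesh = build_mesh(prof, 0.5 * MM)
        expect = np.pi * tube_case.radius**2 * tube_case.length
        assert mesh.total_volume() == pytest.approx(expect, rel=0.01)

    def test_boundary_facets_unique_tags(self):
        prof = build_axisymmetric_profile(make_timepoint_spec("week1"))
        mesh = build_mesh(prof, 0.8 * MM)
        seen = {}
        for tag, facets in mesh.boundary_tags.items():
            for a, b in facets:
                key = (min(a, b), max(a, b))
                assert key not in seen, f"facet tagged twice: {seen[key]} and {tag}"
                seen[key] = tag
        assert len(mesh.boundary_tags["inlet"]) == mesh.n_radial
        assert len(mesh.boundary_tags["wall"]) == mesh.n_axial

    def test_degenerate_cell_size_rejected(self):
        prof = build_axisymmetric_profile(make_timepoint_spec("preop"))
        with pytest.raises(ValueError, match="first"):
            build_mesh(prof, 0.05 * MM, BoundaryLayerSpec(0.065 * MM, 1.2, 5))


class TestYplus:
    def test_preop_stenosis_value(self):
        # first-cell centroid with the printed peak WSS and high-shear viscosity
        yp = estimate_yplus(0.065 * MM, 30.21, 1060.0, 0.00345)
        assert yp == pytest.approx(1.69, abs=0.01)

    def test_sqrt_scaling_in_wall_shear(self):
        y1 = estimate_yplus(0.065 * MM, 10.0, 1060.0, 0.00345)
        y4 = estimate_yplus(0.065 * MM, 40.0, 1060.0, 0.00345)
        assert y4 == pytest.approx(2.0 * y1, rel=1e-12)

    def test_zero_wall_shear_rejected(self):
        with pytest.raises(ValueError):
            estimate_yplus(0.065 * MM, 0.0, 1060.0, 0.00345)
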