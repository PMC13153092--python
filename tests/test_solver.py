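"""Flow-solver verification: Poiseuille closed forms, conservation, BCs."""

import numpy as np
import pytest

from portaflow import geometry as geo
from portaflow.metrics import ProbePlane, area_averaged_pressure
from portaflow.rheology import FluidProps
from portaflow.solver import (SolverConfig, check_convergence, inlet_profile,
                              solve_steady, wall_shear)
from portaflow.windkessel import WK3Params, steady_pressure

WK = WK3Params(Rc=1e7, Rd=1e8, C=1e-8)


class TestInletProfile:
    def test_parabolic_centerline_and_wall(self):
        prof = inlet_profile(0.5, 2e-3)
        assert prof.velocity(0.0) == pytest.approx(0.5)
        assert prof.velocity(2e-3) == pytest.approx(0.0, abs=1e-15)

    def test_volumetric_flow_is_half_peak_times_area(self):
        R, peak = 2e-3, 0.5
        prof = inlet_profile(peak, R)
        assert prof.total_flow == pytest.approx(np.pi * R**2 * peak / 2.0, rel=1e-12)

    def test_plug_flow(self):
        R = 2e-3
        prof = inlet_profile(0.3, R, kind="plug")
        assert prof.velocity(0.9 * R) == pytest.approx(0.3)
        assert prof.total_flow == pytest.approx(np.pi * R**2 * 0.3, rel=1e-12)

    def test_annulus_flows_partition_the_disk(self):
        prof = inlet_profile(0.4, 1.5e-3)
        edges = np.linspace(0.0, 1.5e-3, 7)
        parts = prof.annulus_flow(edges[:-1], edges[1:])
        assert np.sum(parts) == pytest.approx(prof.total_flow, rel=1e-12)


class TestPoiseuille:
    def test_converged_with_mass_conservation(self, tube_field):
        assert tube_field.converged
        assert tube_field.mass_error <= 0.005

    def test_pressure_drop_matches_closed_form(self, tube_case, tube_field):
        z0, z1 = 2e-3, 18e-3
        p0 = area_averaged_pressure(tube_field, ProbePlane(z0, "pre_stenotic"))
        p1 = area_averaged_pressure(tube_field, ProbePlane(z1, "post_stenotic"))
        expect = tube_case.dpdz * (z1 - z0)
        assert (p0 - p1) == pytest.approx(expect, rel=0.02)

    def test_wall_shear_matches_closed_form(self, tube_case, tube_field):
        n = len(tube_field.wall_shear)
        mid = tube_field.wall_shear[n // 3: 2 * n // 3]
        assert np.median(mid) == pytest.approx(tube_case.tau_wall, rel=0.03)

    def test_wall_shear_operator_consistent(self, tube_case, tube_field):
        tau = wall_shear(tube_field, tube_field.mesh, tube_case.fluid())
        assert np.array_equal(tau, tube_field.wall_shear)
        assert np.all(tau >= 0.0)

    def test_wall_shear_rejected_off_wall(self, tube_case, tube_field):
        with pytest.raises(ValueError, match="wall"):
            wall_shear(tube_field, tube_field.mesh, tube_case.fluid(),
                       boundary="inlet")

    def test_outlet_pressure_satisfies_wk3_fixed_point(self, tube_field):
        expect = steady_pressure(tube_field.outlet_flux, WK)
        assert tube_field.outlet_pressure == pytest.approx(expect, rel=1e-3)


@pytest.fixture(scope="module")
def small_mesh(tube_case):
    prof = geo.build_axisymmetric_profile(tube_case.spec(), 60)
    return geo.build_mesh(prof, 0.8e-3)


class TestNullAndLinearity:
    def test_zero_inflow_gives_null_field(self, tube_case, small_mesh):
        field = solve_steady(small_mesh, tube_case.fluid(),
                             inlet_profile(0.0, tube_case.radius), WK,
                             SolverConfig(max_steps=60, monitor_window=30))
        assert field.converged
        assert np.abs(field.cell_velocity).max() == 0.0
        assert np.allclose(field.cell_pressure, WK.Pd, atol=1e-12)
        assert np.all(field.wall_shear == 0.0)

    def test_stokes_regime_pressure_scales_linearly(self, tube_case, small_mesh):
        # Newtonian creeping flow: scaling the inlet velocity by s scales dp by s
        fluid = FluidProps(density=tube_case.rho, rheology=0.035)
        cfg = SolverConfig(max_steps=300, monitor_window=50)
        drops = []
        for peak in (1e-3, 3e-3):
            f = solve_steady(small_mesh, fluid,
                             inlet_profile(peak, tube_case.radius), WK, cfg)
            p0 = area_averaged_pressure(f, ProbePlane(3e-3, "pre_stenotic"))
            p1 = area_averaged_pressure(f, ProbePlane(17e-3, "post_stenotic"))
            drops.append(p0 - p1)
        assert drops[1] == pytest.approx(3.0 * drops[0], rel=0.01)

    def test_determinism_bitwise_monitors(self, tube_case, small_mesh):
        cfg = SolverConfig(max_steps=40, monitor_window=20, residual_tol=1e-30)
        runs = []
        for _ in range(2):
            f = solve_steady(small_mesh, tube_case.fluid(),
                             inlet_profile(tube_case.peak_velocity,
                                           tube_case.radius), WK, cfg)
            runs.append(f)
        assert np.array_equal(runs[0].monitors["outlet_flow"],
                              runs[1].monitors["outlet_flow"])
        assert np.array_equal(runs[0].residual_history, runs[1].residual_history)
        assert np.array_equal(runs[0].cell_pressure, runs[1].cell_pressure)

    def test_missing_outlet_params_rejected(self, tube_case, small_mesh):
        with pytest.raises(KeyError, match="outlet"):
            solve_steady(small_mesh, tube_case.fluid(),
                         inlet_profile(0.1, tube_case.radius),
                         {"wrong_tag": WK}, SolverConfig(max_steps=5,
                                                         monitor_window=2))


class TestStenoticRun:
    """Properties of the converged pre-angioplasty field (shared study run)."""

    def test_jet_amplification_at_throat(self, preop_report):
        # stenotic peak exceeds the pre-stenotic peak by well over 2.5x
        assert preop_report.pvv_ratio >= 2.5

    def test_max_wss_within_throat_segment(self, longitudinal_run):
        rep = longitudinal_run[0]["preop"]
        assert rep.wss_max["stenotic"] == max(rep.wss_max.values())

    def test_mass_conserved(self, longitudinal_run):
        for rep in longitudinal_run[0].values():
            assert rep.mass_error <= 0.005

    def test_positive_gradient_across_throat(self, preop_report):
        assert preop_report.trans_stenotic_gradient > 0.0

    def test_laminar_regime(self, longitudinal_run):
        for rep in longitudinal_run[0].values():
            assert 0.0 < rep.reynolds_max < 2000.0


class TestCheckConvergence:
    CFG = SolverConfig(monitor_window=10, monitor_tol=1e-3)

    def test_stable_monitors_and_low_residual(self):
        hist = np.full(20, 1e-6)
        mons = {"q": np.ones(20), "p": np.full(20, 5.0)}
        assert check_convergence(hist, mons, self.CFG)

    def test_oscillating_monitor_fails(self):
        hist = np.full(20, 1e-6)
        q = np.ones(20)
        q[::2] *= 1.05                      # 5% span
        assert not check_convergence(hist, {"q": q}, self.CFG)

    def test_high_residual_fails(self):
        hist = np.full(20, 1e-3)
        assert not check_convergence(hist, {"q": np.ones(20)}, self.CFG)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            check_convergence(np.ones(3), {}, self.CFG)
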