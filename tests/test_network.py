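"""0D network: segment resistances, stenosis element, branch-split solve."""

import numpy as np
import pytest

from portaflow import geometry as geo
from portaflow.network import (BifurcationNetwork, Segment, StenosisElement,
                               segment_resistance, solve_network, stenosis_loss)
from portaflow.rheology import FluidProps
from portaflow.windkessel import RAPV, RPPV, WK3Params

NEWTONIAN = FluidProps(density=1060.0, rheology=3.5e-3)


def poiseuille_r(mu, L, R):
    return 8.0 * mu * L / (np.pi * R**4)


class TestSegmentResistance:
    def test_constant_radius_closed_form(self):
        seg = Segment(length=30e-3, radius=2.5e-3)
        expect = poiseuille_r(3.5e-3, 30e-3, 2.5e-3)
        got = segment_resistance(seg, 3.5e-3)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(6.84e6, rel=2e-3)

    def test_profile_quadrature_of_constant_matches_closed_form(self, tube_case):
        prof = geo.build_axisymmetric_profile(tube_case.spec(), 80)
        seg = Segment(length=prof.length, profile=prof)
        expect = poiseuille_r(3.5e-3, prof.length, tube_case.radius)
        assert segment_resistance(seg, 3.5e-3) == pytest.approx(expect, rel=1e-10)

    def test_r_fourth_power_scaling(self):
        r1 = segment_resistance(Segment(length=0.03, radius=2e-3), 3.5e-3)
        r2 = segment_resistance(Segment(length=0.03, radius=1e-3), 3.5e-3)
        assert r2 == pytest.approx(16.0 * r1, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            Segment(length=0.03, radius=0.0)
        with pytest.raises(ValueError):
            segment_resistance(Segment(length=0.03, radius=1e-3), 0.0)


class TestStenosisLoss:
    ELEM = StenosisElement(throat_area=1e-5, reference_area=2e-5,
                           viscous_resistance=0.0, expansion_coefficient=1.0)

    def test_zero_flow_zero_loss(self):
        assert stenosis_loss(self.ELEM, 0.0, 1060.0) == 0.0

    def test_unit_throat_velocity_half_area(self):
        # V_s = 1 m/s, As/A0 = 0.5, Kt = 1: inertial term = 0.5*1060*0.25
        q = self.ELEM.throat_area * 1.0
        assert stenosis_loss(self.ELEM, q, 1060.0) == pytest.approx(132.5, rel=1e-12)

    def test_odd_in_flow(self):
        q = 3e-6
        assert stenosis_loss(self.ELEM, -q, 1060.0) == pytest.approx(
            -stenosis_loss(self.ELEM, q, 1060.0), rel=1e-12)

    def test_no_expansion_purely_viscous(self):
        elem = StenosisElement(throat_area=1e-5, reference_area=1e-5,
                               viscous_resistance=1e8)
        assert stenosis_loss(elem, 2e-6, 1060.0) == pytest.approx(200.0, rel=1e-12)

    def test_invalid_areas(self):
        with pytest.raises(ValueError):
            StenosisElement(throat_area=2e-5, reference_area=1e-5,
                            viscous_resistance=0.0)


def _network(branches, terminals):
    return BifurcationNetwork(trunk=None, branches=branches, terminals=terminals)


class TestSolveNetwork:
    def test_symmetric_branches_split_exactly_half(self):
        seg = Segment(length=0.03, radius=3e-3)
        term = WK3Params(Rc=2e8, Rd=2e9, C=1e-8)
        topo = _network({"A": seg, "B": seg}, {"A": term, "B": term})
        sol = solve_network(1e-5, topo, fluid=NEWTONIAN)
        assert sol.branch_flows["A"] == sol.branch_flows["B"] == 5e-6
        assert sol.iterations == 0

    def test_clinical_terminals_resistor_divider(self):
        # negligible segment resistance: split follows (Rc+Rd) alone
        seg = Segment(length=1e-6, radius=5e-2)
        topo = _network({"RAPV": seg, "RPPV": seg}, {"RAPV": RAPV, "RPPV": RPPV})
        sol = solve_network(1.716e-5, topo, fluid=NEWTONIAN)
        got = sol.branch_flows["RAPV"] / sol.branch_flows["RPPV"]
        expect = RPPV.total_resistance / RAPV.total_resistance
        assert got == pytest.approx(expect, abs=1e-6)
        assert got == pytest.approx(0.9747, abs=1e-3)

    def test_linear_network_matches_resistor_algebra(self):
        # Kt = 0 and Newtonian rheology: brute-force conductance solution
        sa = Segment(length=0.03, radius=2.5e-3)
        sp = Segment(length=0.04, radius=3.65e-3)
        topo = _network({"A": sa, "B": sp}, {"A": RAPV, "B": RPPV})
        q_in = 1.6e-5
        sol = solve_network(q_in, topo, fluid=NEWTONIAN)
        ga = 1.0 / (segment_resistance(sa, 3.5e-3) + RAPV.total_resistance)
        gb = 1.0 / (segment_resistance(sp, 3.5e-3) + RPPV.total_resistance)
        assert sol.branch_flows["A"] == pytest.approx(q_in * ga / (ga + gb), rel=1e-10)
        assert sol.iterations <= 1        # linear: one Newton step

    def test_flow_conservation(self):
        sa = Segment(length=0.03, radius=2e-3)
        sb = Segment(length=0.03, radius=3e-3)
        topo = _network({"A": sa, "B": sb}, {"A": RAPV, "B": RPPV})
        sol = solve_network(1e-5, topo, fluid=FluidProps())
        total = sum(sol.branch_flows.values())
        assert total == pytest.approx(1e-5, rel=1e-10)

    def test_kirchhoff_path_pressures_agree(self):
        sa = Segment(length=0.03, radius=2e-3)
        sb = Segment(length=0.05, radius=3e-3)
        topo = _network({"A": sa, "B": sb}, {"A": RAPV, "B": RPPV})
        fluid = FluidProps()
        sol = solve_network(1.2e-5, topo, fluid=fluid)
        drops = {}
        for tag, seg in topo.branches.items():
            q = sol.branch_flows[tag]
            gamma = 8.0 * (q / (np.pi * seg.radius**2)) / (2 * seg.radius)
            r = segment_resistance(seg, float(fluid.viscosity(gamma)))
            t = topo.terminals[tag]
            drops[tag] = q * (r + t.total_resistance) + t.Pd
        assert drops["A"] == pytest.approx(drops["B"], abs=1e-6)

    def test_missing_terminal_named(self):
        topo = _network({"A": Segment(length=0.03, radius=2e-3)}, {"A": RAPV})
        with pytest.raises(KeyError, match="A"):
            solve_network(1e-5, topo, terminals={"B": RPPV}, fluid=NEWTONIAN)

    def test_mismatched_tags_rejected(self):
        with pytest.raises(ValueError, match="B"):
            _network({"A": Segment(length=0.03, radius=2e-3)},
                     {"A": RAPV, "B": RPPV})
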