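"""Shared fixtures: closed-form verification cases and study-scale runs.

Session-scoped fixtures run the expensive simulations once; every test that
checks a property of the converged fields reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from portaflow import geometry as geo
from portaflow.geometry import BoundaryLayerSpec, VesselTimepointSpec
from portaflow.pipeline import StudyConfig, run_longitudinal
from portaflow.rheology import FluidProps
from portaflow.solver import SolverConfig, inlet_profile, solve_steady
from portaflow.windkessel import WK3Params


class TubeCase:
    """Straight-tube Poiseuille verification constants (Newtonian)."""

    radius = 2.5e-3           # m
    length = 20e-3            # m
    mu = 3.5e-3               # Pa.s
    flow = 1e-5               # m^3/s
    rho = 1060.0

    @property
    def peak_velocity(self):
        return 2.0 * self.flow / (np.pi * self.radius**2)

    @property
    def dpdz(self):
        return 8.0 * self.mu * self.flow / (np.pi * self.radius**4)

    @property
    def tau_wall(self):
        return 4.0 * self.mu * self.flow / (np.pi * self.radius**3)

    def spec(self):
        d = 2.0 * self.radius
        return VesselTimepointSpec(
            label="tube", inlet_diameter=d, prestenotic_max_diameter=d,
            throat_diameter=d, stenosis_length=5e-3,
            downstream_trunk_diameter=d, branch_diameters=(d, d),
            branch_lengths=(10e-3, 10e-3),
            inlet_peak_velocity=self.peak_velocity, total_length=self.length)

    def fluid(self):
        return FluidProps(density=self.rho, rheology=self.mu)


@pytest.fixture(scope="session")
def tube_case():
    return TubeCase()


@pytest.fixture(scope="session")
def tube_field(tube_case):
    """Converged Poiseuille flow on the fine default-layered mesh."""
    profile = geo.build_axisymmetric_profile(tube_case.spec(), 100)
    mesh = geo.build_mesh(profile, 0.4e-3)
    field = solve_steady(
        mesh, tube_case.fluid(),
        inlet_profile(tube_case.peak_velocity, tube_case.radius),
        WK3Params(Rc=1e7, Rd=1e8, C=1e-8),
        SolverConfig(max_steps=800, monitor_window=50))
    return field


@pytest.fixture(scope="session")
def study_config():
    """Default study configuration (clinical presets, 0.65 mm mesh)."""
    return StudyConfig()


@pytest.fixture(scope="session")
def longitudinal_run(study_config):
    """Reports + longitudinal comparisons for the three timepoint presets."""
    return run_longitudinal(study_config)


@pytest.fixture(scope="session")
def preop_report(longitudinal_run):
    return longitudinal_run[0]["preop"]


@pytest.fixture(scope="session")
def uniform_ladder_config(tube_case):
    """Richardson-style uniform-grid ladder configuration for the tube."""
    sizes = [tube_case.radius / n for n in (8, 10, 12, 16)]
    return StudyConfig(
        fluid=tube_case.fluid(),
        solver=SolverConfig(max_steps=1500, residual_tol=1e-8, monitor_window=50),
        boundary_layer=BoundaryLayerSpec(sizes[0], 1.0, 1),
        grid_sizes=sizes)
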