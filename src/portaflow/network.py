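"""Lumped (0D) model of the trunk–bifurcation–terminal portal system.

Each vessel segment contributes an integrated Poiseuille resistance

    R = int 8*mu_eff / (pi * r(z)^4) dz,

evaluated by quadrature over an arbitrary radius profile (exactly 8*mu*L/
(pi*R^4) for a constant radius).  The stenosis is a nonlinear element
combining a viscous resistance with a Borda–Carnot sudden-expansion loss

    dp = R_v * Q + Kt * (rho/2) * V_s * |V_s| * (1 - As/A0)^2,   V_s = Q/As,

odd in Q (Kt defaults to 1).  Terminals are steady three-element Windkessels,
i.e. pure resistances Rc + Rd referenced to Pd.  Branch flows are found by
damped Newton iteration on the leaf flows until the nodal pressure mismatch
is below 1e-8 Pa; with all inertial coefficients zero the network is linear
and Newton converges in a single step.

Effective viscosity per segment defaults to the Carreau–Yasuda value at the
Poiseuille wall shear rate 8*V_mean/D of the segment, recomputed at every
Newton iterate.

Note: with the default terminal parameter sets the two branch totals are
nearly equal (split ratio ~0.975), so the clinically observed ~2:1
anterior/posterior flow asymmetry is a patient-geometry effect this 0D model
does not claim to reproduce; comparison reports document the discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.integrate import quad

from .geometry import AxisymmetricProfile
from .rheology import FluidProps

__all__ = [
    "Segment",
    "StenosisElement",
    "NetworkSolution",
    "BifurcationNetwork",
    "segment_resistance",
    "stenosis_loss",
    "solve_network",
]


@dataclass(frozen=True)
class Segment:
    """A vessel segment: constant radius or an axisymmetric radius profile."""

    length: float                               # m
    radius: float | None = None                 # m, constant-radius shorthand
    profile: AxisymmetricProfile | None = None  # overrides radius when given
    fluid: FluidProps | None = None             # rheology handle (optional)

    def __post_init__(self) -> None:
        if self.profile is None:
            if self.radius is None or self.radius <= 0.0:
                raise ValueError("segment needs a positive radius or a profile")
        if self.length <= 0.0:
            raise ValueError("segment length must be > 0")

    def radius_at(self, z):
        if self.profile is not None:
            return self.profile.radius(z)
        return np.full_like(np.asarray(z, float), self.radius)

    @property
    def min_radius(self) -> float:
        if self.profile is not None:
            return float(self.profile.r.min())
        return float(self.radius)

    @property
    def mean_diameter(self) -> float:
        if self.profile is not None:
            return 2.0 * float(self.profile.r.mean())
        return 2.0 * self.radius


def segment_resistance(segment: Segment, mu_eff: float) -> float:
    """Integrated Poiseuille resistance (Pa·s/m^3) of a segment.

    R = int 8 mu / (pi r(z)^4) dz; the constant-radius case reduces to the
    closed form 8 mu L / (pi R^4) exactly.
    """
    if mu_eff <= 0.0:
        raise ValueError("mu_eff must be > 0")
    if segment.min_radius <= 0.0:
        raise ValueError("segment radius must be > 0 along the whole profile")
    if segment.profile is None:
        return 8.0 * mu_eff * segment.length / (np.pi * segment.radius**4)
    z0, z1 = float(segment.profile.z[0]), float(segment.profile.z[-1])
    val, _ = quad(lambda z: 8.0 * mu_eff / (np.pi * float(segment.profile.radius(z)) ** 4),
                  z0, z1, limit=200)
    return float(val)


@dataclass(frozen=True)
class StenosisElement:
    """0D stenosis surrogate: viscous resistance + Borda–Carnot expansion loss."""

    throat_area: float               # As, m^2
    reference_area: float            # A0 (distal reference), m^2
    viscous_resistance: float        # Pa·s/m^3
    expansion_coefficient: float = 1.0   # Kt

    def __post_init__(self) -> None:
        if not (0.0 < self.throat_area <= self.reference_area):
            raise ValueError("require 0 < throat_area <= reference_area")
        if self.expansion_coefficient < 0.0:
            raise ValueError("expansion coefficient Kt must be >= 0")


def stenosis_loss(element: StenosisElement, Q: float, rho: float) -> float:
    """Pressure loss (Pa) across the stenosis element at flow Q; odd in Q."""
    vs = Q / element.throat_area
    inertial = element.expansion_coefficient * 0.5 * rho * vs * abs(vs) \
        * (1.0 - element.throat_area / element.reference_area) ** 2
    return element.viscous_resistance * Q + inertial


@dataclass(frozen=True)
class NetworkSolution:
    """Branch flows (m^3/s per terminal tag), nodal pressures (Pa), iterations."""

    branch_flows: dict
    nodal_pressures: dict
    iterations: int

    @property
    def total_flow(self) -> float:
        return float(sum(self.branch_flows.values()))


@dataclass(frozen=True)
class BifurcationNetwork:
    """Trunk (optionally with a stenosis element) feeding N terminal branches.

    The trunk runs from the inlet to the junction; each branch segment ends in
    a steady WK3 terminal.  ``terminals`` maps tag -> WK3Params; ``branches``
    maps the same tags -> Segment.
    """

    trunk: Segment | None
    branches: dict
    terminals: dict
    stenosis: StenosisElement | None = None

    def __post_init__(self) -> None:
        missing = sorted(set(self.branches) ^ set(self.terminals))
        if missing:
            raise ValueError(f"branch/terminal tags mismatch: {missing}")
        if not self.branches:
            raise ValueError("network needs at least one branch")


def _mu_eff(seg: Segment, Q: float, fluid: FluidProps | None) -> float:
    """Carreau–Yasuda viscosity at the Poiseuille wall shear rate 8 V/D."""
    fl = seg.fluid or fluid
    if fl is None:
        raise ValueError("no fluid properties available for segment")
    d = 2.0 * seg.min_radius if seg.profile is not None else 2.0 * seg.radius
    v = abs(Q) / (np.pi * (d / 2.0) ** 2)
    gamma = 8.0 * v / d
    return float(fl.viscosity(gamma))


def solve_network(
    inlet_flow: float,
    topology: BifurcationNetwork,
    terminals: dict | None = None,
    fluid: FluidProps | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NetworkSolution:
    """Solve the branch flow split by damped Newton iteration.

    Unknowns are the first N-1 leaf flows (the last follows from mass
    conservation, so junction conservation holds to round-off by
    construction).  Residuals are the pairwise differences of the terminal
    path pressures — at the solution, the pressure drop from the junction to
    ``Pd`` is identical along every path (Kirchhoff consistency) to within
    ``tol`` (Pa).  Raises with the last mismatch if ``max_iter`` is exceeded.
    """
    terms = terminals if terminals is not None else topology.terminals
    tags = sorted(topology.branches)
    missing = [t for t in tags if t not in terms]
    if missing:
        raise KeyError(f"no terminal parameters for branch(es) {missing}")
    n = len(tags)
    fluid = fluid or FluidProps()

    def path_pressure(tag: str, q: float) -> float:
        """Pressure at the junction needed to push q through branch `tag`."""
        seg = topology.branches[tag]
        t = terms[tag]
        r_seg = segment_resistance(seg, _mu_eff(seg, q, fluid))
        return q * (r_seg + t.Rc + t.Rd) + t.Pd

    def residuals(qs: np.ndarray) -> np.ndarray:
        p = [path_pressure(tag, q) for tag, q in zip(tags, qs)]
        return np.array([p[k] - p[-1] for k in range(n - 1)])

    if n == 1:
        qs = np.array([inlet_flow])
        iterations = 0
    else:
        qs = np.full(n, inlet_flow / n)
        iterations = 0
        while True:
            res = residuals(qs)
            if np.max(np.abs(res)) < tol:
                break
            if iterations >= max_iter:
                raise RuntimeError(
                    f"network Newton failed to converge in {max_iter} iterations; "
                    f"last pressure mismatch {np.max(np.abs(res)):.3e} Pa")
            # numerical Jacobian wrt the first n-1 flows (last = balance);
            # relative step large enough that round-off in the Pa-scale
            # residuals stays far below the 1e-8 Pa tolerance
            jac = np.zeros((n - 1, n - 1))
            h = max(abs(inlet_flow), 1e-9) * 1e-3
            for k in range(n - 1):
                dq = np.zeros(n)
                dq[k] = h
                dq[-1] = -h
                jac[:, k] = (residuals(qs + dq) - res) / h
            step = np.linalg.solve(jac, -res)
            full = np.concatenate([step, [-step.sum()]])
            qs = qs + full
            iterations += 1

    p_junction = path_pressure(tags[0], qs[0])
    p_inlet = p_junction
    if topology.trunk is not None:
        r_trunk = segment_resistance(topology.trunk,
                                     _mu_eff(topology.trunk, inlet_flow, fluid))
        p_inlet += r_trunk * inlet_flow
    if topology.stenosis is not None:
        p_inlet += stenosis_loss(topology.stenosis, inlet_flow, fluid.density)

    return NetworkSolution(
        branch_flows={tag: float(q) for tag, q in zip(tags, qs)},
        nodal_pressures={"inlet": float(p_inlet), "junction": float(p_junction)},
        iterations=iterations,
    )
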