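"""Three-element Windkessel (RCR) terminal model for portal-vein outlets.

Each outlet is loaded with a characteristic impedance ``Rc`` in series with a
parallel combination of peripheral resistance ``Rd`` and compliance ``C``,
referenced to a downstream pressure ``Pd``.  The compliance-chamber pressure
``Pc`` obeys

    C dPc/dt = Q - (Pc - Pd)/Rd,

and the pressure imposed on the 3D/0D solver at the outlet is P = Pc + Q*Rc.
At the dPc/dt = 0 fixed point this reduces to a pure resistance:
P = Pd + Q*(Rc + Rd).

``Pd`` is a gauge reference (0 Pa by default), so all reported pressures are
relative, not absolute physiological pressures.

Default parameter sets for the right anterior (RAPV) and right posterior
(RPPV) portal-vein branches are clinically calibrated values:

======  ===========  ===========  ===========
outlet  Rc Pa·s/m³   Rd Pa·s/m³   C m³/Pa
======  ===========  ===========  ===========
RAPV    2.7175e8     1.9017e9     9.4916e-9
RPPV    2.4875e8     1.8697e9     9.4916e-9
======  ===========  ===========  ===========

The RCR ODE is advanced with backward Euler (unconditionally stable; shares
the flow solver's time step).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "WK3Params",
    "WK3State",
    "RAPV",
    "RPPV",
    "DEFAULT_OUTLETS",
    "steady_pressure",
    "step",
    "couple",
    "parallel_equivalent",
]


@dataclass(frozen=True)
class WK3Params:
    """RCR Windkessel parameters: Rc, Rd in Pa·s/m³, C in m³/Pa, Pd in Pa."""

    Rc: float
    Rd: float
    C: float
    Pd: float = 0.0

    def __post_init__(self) -> None:
        if self.Rc <= 0.0 or self.Rd <= 0.0 or self.C <= 0.0:
            raise ValueError("Rc, Rd and C must all be > 0")

    @property
    def total_resistance(self) -> float:
        """Steady terminal resistance Rc + Rd (Pa·s/m³)."""
        return self.Rc + self.Rd

    @property
    def time_constant(self) -> float:
        """Exponential relaxation time Rd*C (s)."""
        return self.Rd * self.C


@dataclass(frozen=True)
class WK3State:
    """Compliance-chamber pressure Pc (Pa) at time t (s)."""

    Pc: float
    t: float = 0.0


RAPV = WK3Params(Rc=2.7175e8, Rd=1.9017e9, C=9.4916e-9, Pd=0.0)
RPPV = WK3Params(Rc=2.4875e8, Rd=1.8697e9, C=9.4916e-9, Pd=0.0)

DEFAULT_OUTLETS: dict[str, WK3Params] = {"RAPV": RAPV, "RPPV": RPPV}


def steady_pressure(Q: float, params: WK3Params) -> float:
    """Steady outlet pressure P = Pd + Q*(Rc + Rd) (the dPc/dt = 0 fixed point)."""
    return params.Pd + Q * (params.Rc + params.Rd)


def step(state: WK3State, Q: float, dt: float, params: WK3Params) -> WK3State:
    """Advance the compliance pressure one backward-Euler step of size ``dt``.

    Solves C (Pc' - Pc)/dt = Q - (Pc' - Pd)/Rd for Pc'; unconditionally
    stable for any dt > 0.
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    tau = params.Rd * params.C
    pc_new = (state.Pc + dt / params.C * Q + dt / tau * params.Pd) / (1.0 + dt / tau)
    return WK3State(Pc=pc_new, t=state.t + dt)


def outlet_pressure(state: WK3State, Q: float, params: WK3Params) -> float:
    """Pressure the outlet imposes on the solver: P = Pc + Q*Rc."""
    return state.Pc + Q * params.Rc


def couple(
    outlet_flux: Mapping[str, float],
    states: Mapping[str, WK3State],
    params_per_outlet: Mapping[str, WK3Params],
    dt: float,
) -> tuple[dict[str, float], dict[str, WK3State]]:
    """Advance every tagged outlet one step and return its imposed pressure.

    Parameters map outlet tag -> value; a flux for a tag with no parameter set
    is rejected naming the offending outlet.  Deterministic given (states,
    fluxes); output ordering follows the flux mapping.
    """
    missing = [tag for tag in outlet_flux if tag not in params_per_outlet]
    if missing:
        raise KeyError(
            f"no WK3 parameters for outlet(s) {missing}; "
            f"configured outlets: {sorted(params_per_outlet)}"
        )
    pressures: dict[str, float] = {}
    new_states: dict[str, WK3State] = {}
    for tag, Q in outlet_flux.items():
        p = params_per_outlet[tag]
        st = states.get(tag, WK3State(Pc=p.Pd))
        st = step(st, Q, dt, p)
        new_states[tag] = st
        pressures[tag] = outlet_pressure(st, Q, p)
    return pressures, new_states


def parallel_equivalent(params: Sequence[WK3Params]) -> WK3Params:
    """Single WK3 equivalent (in the steady sense) of terminals in parallel.

    Rc is the parallel combination of the characteristic impedances, the total
    steady resistance is the parallel combination of the Rc+Rd sums, and
    compliances add.  Exact at steady state; an approximation transiently.
    All terminals must share the same Pd.
    """
    if not params:
        raise ValueError("need at least one terminal")
    pd = params[0].Pd
    if any(p.Pd != pd for p in params):
        raise ValueError("parallel terminals must share Pd")
    inv_rc = sum(1.0 / p.Rc for p in params)
    inv_rt = sum(1.0 / (p.Rc + p.Rd) for p in params)
    rc = 1.0 / inv_rc
    rt = 1.0 / inv_rt
    return WK3Params(Rc=rc, Rd=rt - rc, C=sum(p.C for p in params), Pd=pd)
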