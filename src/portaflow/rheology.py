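"""Blood rheology: Carreau–Yasuda shear-thinning viscosity and the laminar-regime check.

Whole blood is strongly shear-thinning at the low shear rates typical of the
portal venous system.  The Carreau–Yasuda law interpolates between a zero-shear
plateau ``mu0`` and an infinite-shear plateau ``mu_inf``::

    mu(g) = mu_inf + (mu0 - mu_inf) * [1 + (lam*g)**a] ** ((n - 1)/a)

with relaxation time ``lam`` (s), transition exponent ``a`` and power-law index
``n``.  Defaults are the canonical whole-blood parameter set
(mu0 = 0.056 Pa·s, mu_inf = 3.45e-3 Pa·s, lam = 3.313 s, a = 2, n = 0.3568);
absolute viscous quantities downstream depend on this choice, which is fully
overridable through the ``fluid:`` config block.

Shear rate is defined as the strain-rate tensor magnitude sqrt(2 D:D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CarreauYasudaParams",
    "FluidProps",
    "BLOOD_DENSITY",
    "viscosity",
    "reynolds_number",
    "LAMINAR_RE_LIMIT",
]

#: Blood density used throughout (kg/m^3).
BLOOD_DENSITY = 1060.0

#: Reynolds number below which pipe flow is taken as laminar.
LAMINAR_RE_LIMIT = 2000.0


@dataclass(frozen=True)
class CarreauYasudaParams:
    """Five-parameter Carreau–Yasuda viscosity law for whole blood."""

    mu0: float = 0.056        # zero-shear viscosity, Pa·s
    mu_inf: float = 0.00345   # infinite-shear viscosity, Pa·s
    lam: float = 3.313        # relaxation time, s
    a: float = 2.0            # transition exponent
    n: float = 0.3568         # power-law index

    def __post_init__(self) -> None:
        # equality gives exact Newtonian recovery (constant viscosity)
        if not (self.mu0 >= self.mu_inf > 0.0):
            raise ValueError("require mu0 >= mu_inf > 0")
        if self.lam <= 0.0:
            raise ValueError("relaxation time lam must be > 0")
        if self.a <= 0.0:
            raise ValueError("transition exponent a must be > 0")
        if not (0.0 < self.n <= 1.0):
            raise ValueError("power-law index n must lie in (0, 1]")


@dataclass(frozen=True)
class FluidProps:
    """Density plus either a Carreau–Yasuda law or a constant Newtonian viscosity."""

    density: float = BLOOD_DENSITY
    rheology: CarreauYasudaParams | float = field(default_factory=CarreauYasudaParams)

    def __post_init__(self) -> None:
        if self.density <= 0.0:
            raise ValueError("density must be > 0")
        if isinstance(self.rheology, (int, float)) and self.rheology <= 0.0:
            raise ValueError("Newtonian viscosity must be > 0")

    @property
    def is_newtonian(self) -> bool:
        return not isinstance(self.rheology, CarreauYasudaParams)

    def viscosity(self, gamma_dot):
        """Dynamic viscosity (Pa·s) at shear rate ``gamma_dot`` (1/s, scalar or array)."""
        if self.is_newtonian:
            return np.broadcast_to(float(self.rheology), np.shape(gamma_dot)).copy() \
                if np.ndim(gamma_dot) else float(self.rheology)
        return viscosity(gamma_dot, self.rheology)

    @property
    def mu_inf(self) -> float:
        """High-shear viscosity scale, used for Reynolds-number estimates."""
        if self.is_newtonian:
            return float(self.rheology)
        return self.rheology.mu_inf


def viscosity(gamma_dot, params: CarreauYasudaParams):
    """Carreau–Yasuda viscosity (Pa·s) at shear rate ``gamma_dot`` (1/s).

    Accepts scalars or arrays; bounded in [mu_inf, mu0] and non-increasing in
    the shear rate for n < 1.  Negative shear rates are rejected (the shear
    rate is a tensor magnitude, hence non-negative by definition).
    """
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0.0):
        raise ValueError("shear rate must be non-negative")
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * (
        1.0 + (params.lam * g) ** params.a
    ) ** ((params.n - 1.0) / params.a)
    return float(mu) if np.ndim(gamma_dot) == 0 else mu


def reynolds_number(rho: float, V: float, D: float, mu: float) -> float:
    """Pipe Reynolds number Re = rho*V*D/mu.

    ``V = 0`` is allowed (returns 0); other arguments must be positive.
    The flow is treated as laminar when Re < 2000.
    """
    if rho <= 0.0 or D <= 0.0 or mu <= 0.0:
        raise ValueError("rho, D and mu must be > 0")
    if V < 0.0:
        raise ValueError("velocity must be >= 0")
    return rho * V * D / mu


def is_laminar(re: float) -> bool:
    """Laminar-regime check used by the pipeline (Re < 2000)."""
    return re < LAMINAR_RE_LIMIT
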