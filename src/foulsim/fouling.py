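"""Deposit-layer kinetics at the membrane surface.

The loose layer of neutral casein on the cation-exchange surface is described
by a single state, its thickness alpha (m), obeying

    d(alpha)/dt = -a * alpha + (b / c0_dep) * c_HCas0(x=0)

where a (1/s) is the dissolution rate, b (m/s) the formation rate and
c0_dep = rho / M the molar concentration of the condensed casein phase.  The
matching heterogeneous surface flux returns exactly the casein exchanged with
the solution, so the pair conserves casein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError, DomainError

__all__ = ["DepositParams", "deposit_rate", "surface_reaction_flux",
           "deposit_mass_per_area"]

#: Active membrane area used for absolute-mass reporting, m^2 (10 cm^2).
ACTIVE_AREA_M2 = 10e-4


@dataclass(frozen=True)
class DepositParams:
    """Deposit kinetics and material constants.

    rho is the density of the casein deposit (1.1 g/cm^3 = 1100 kg/m^3) and
    M the casein molar mass (2062 g/mol); their ratio c0_dep ~ 533.5 mol/m^3
    is the concentration of the condensed phase.
    """

    a: float = 1.0          # 1/s
    b: float = 5e-4         # m/s
    rho: float = 1100.0     # kg/m^3
    M: float = 2.062        # kg/mol
    c0_dep: float = field(default=1100.0 / 2.062)  # mol/m^3

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b < 0:
            raise ConfigurationError("require a > 0 and b >= 0")
        if self.rho <= 0 or self.M <= 0:
            raise ConfigurationError("rho and M must be positive")
        if not math.isclose(self.c0_dep, self.rho / self.M, rel_tol=1e-12):
            raise ConfigurationError(
                f"c0_dep = {self.c0_dep:g} inconsistent with rho/M = {self.rho / self.M:g}"
            )

    @classmethod
    def make(cls, a: float = 1.0, b: float = 5e-4, rho: float = 1100.0,
             M: float = 2.062) -> "DepositParams":
        return cls(a=a, b=b, rho=rho, M=M, c0_dep=rho / M)


def deposit_rate(alpha: float, c_surface: float, params: DepositParams) -> float:
    """Growth rate d(alpha)/dt (m/s) of the deposit layer.

    Linear dissolution (-a*alpha) against first-order attachment of the
    neutral casein available at the surface.  The fixed point for constant
    surface concentration is alpha* = b*c_surface / (a*c0_dep).
    """
    if alpha < 0 or c_surface < 0:
        raise DomainError("alpha and c_surface must be non-negative")
    return -params.a * alpha + params.b * c_surface / params.c0_dep


def surface_reaction_flux(alpha: float, c_surface: float,
                          params: DepositParams) -> float:
    """Heterogeneous flux of HCas0 into the solution at x = 0 (mol/(m^2 s)).

    R_s = a*alpha*c0_dep - b*c_surface; positive when the layer dissolves.
    Identically R_s = -c0_dep * deposit_rate, so solution and deposit
    exchange casein conservatively.
    """
    if alpha < 0 or c_surface < 0:
        raise DomainError("alpha and c_surface must be non-negative")
    return params.a * alpha * params.c0_dep - params.b * c_surface


def deposit_mass_per_area(alpha: float, rho: float = 1100.0) -> float:
    """Deposit mass per membrane area in mg/cm^2 for thickness alpha (m).

    rho*alpha is kg/m^2; 1 kg/m^2 = 100 mg/cm^2.
    """
    if alpha < 0:
        raise DomainError("alpha must be non-negative")
    return rho * alpha * 100.0
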