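"""Species registry, protonation chemistry and bulk-composition construction.

The model solution is a sodium caseinate / KCl electrolyte with seven
transported or reacting species: Na+, K+, H+, Cl-, OH-, the caseinate anion
Cas- and the neutral (insoluble) casein molecule HCas0.  Two homogeneous
reactions couple them:

* casein protonation       HCas0 <-> H+ + Cas-     (Ka = k1 / k_m1)
* water autoprotolysis     H2O   <-> H+ + OH-      (Kw = c_H * c_OH)

All quantities are SI volume-based: concentrations in mol/m^3 (so pH p
corresponds to c_H = 10**(3 - p) mol/m^3), diffusivities in m^2/s,
conductivity in S/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError, InfeasibleCompositionError

__all__ = [
    "SPECIES_NAMES",
    "Species",
    "SpeciesSet",
    "PhysicalConstants",
    "ReactionParams",
    "BulkComposition",
    "build_species_table",
    "reaction_sources",
    "equilibrium_speciation",
    "conductivity",
    "build_bulk_composition",
    "stokes_einstein_diffusivity",
    "ph_of",
]

#: Canonical species ordering used by every array in the package.
SPECIES_NAMES = ("Na+", "K+", "H+", "Cl-", "OH-", "Cas-", "HCas0")

#: Indices of the species in the canonical order.
I_NA, I_K, I_H, I_CL, I_OH, I_CAS, I_HCAS0 = range(7)

_DEFAULT_CHARGES = {
    "Na+": 1, "K+": 1, "H+": 1, "Cl-": -1, "OH-": -1, "Cas-": -1, "HCas0": 0,
}

# Infinite-dilution diffusion coefficients, m^2/s.  The caseinate value is
# consistent with a Stokes-Einstein radius of ~3.7 nm (see
# stokes_einstein_diffusivity); the neutral casein molecule is taken an order
# of magnitude slower still, reflecting its aggregated state.
_DEFAULT_DIFFUSIVITIES = {
    "Na+": 1.33e-9,
    "K+": 1.98e-9,
    "H+": 9.3e-9,
    "Cl-": 2.03e-9,
    "OH-": 5.27e-9,
    "Cas-": 6.6e-11,
    "HCas0": 1e-12,
}

_KB = 1.380649e-23  # Boltzmann constant, J/K


@dataclass(frozen=True)
class Species:
    """A transported species: name, charge number and diffusivity (m^2/s)."""

    name: str
    z: int
    D: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ConfigurationError(f"D({self.name}) must be positive, got {self.D}")
        if self.z not in (-1, 0, 1):
            raise ConfigurationError(
                f"z({self.name}) must be in {{-1, 0, +1}}, got {self.z}"
            )


class SpeciesSet:
    """Ordered, immutable collection of the seven model species.

    Exposes the charge and diffusivity vectors in the canonical order
    (`SPECIES_NAMES`) for vectorised transport arithmetic.
    """

    def __init__(self, species: tuple[Species, ...]):
        names = tuple(s.name for s in species)
        if names != SPECIES_NAMES:
            raise ConfigurationError(
                f"species must be exactly {SPECIES_NAMES} in order, got {names}"
            )
        self._species = species
        self._index = {s.name: i for i, s in enumerate(species)}
        self.z = np.array([s.z for s in species], dtype=float)
        self.D = np.array([s.D for s in species], dtype=float)
        self.z.setflags(write=False)
        self.D.setflags(write=False)

    @property
    def names(self) -> tuple[str, ...]:
        return SPECIES_NAMES

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConfigurationError(f"unknown species {name!r}") from None

    def __len__(self) -> int:
        return len(self._species)

    def __iter__(self):
        return iter(self._species)

    def __getitem__(self, key: int | str) -> Species:
        if isinstance(key, str):
            return self._species[self.index(key)]
        return self._species[key]

    def __repr__(self) -> str:
        return f"SpeciesSet({', '.join(s.name for s in self._species)})"


def build_species_table(
    overrides: dict[str, tuple[int, float]] | None = None,
) -> SpeciesSet:
    """Build the seven-species set with default charges and diffusivities.

    Parameters
    ----------
    overrides
        Optional map ``name -> (z, D)`` replacing the default charge number
        and diffusivity of known species.  Unknown names raise
        :class:`ConfigurationError`.
    """
    table = {n: (_DEFAULT_CHARGES[n], _DEFAULT_DIFFUSIVITIES[n]) for n in SPECIES_NAMES}
    if overrides:
        for name, zd in overrides.items():
            if name not in table:
                raise ConfigurationError(f"unknown species in overrides: {name!r}")
            table[name] = (int(zd[0]), float(zd[1]))
    return SpeciesSet(tuple(Species(n, *table[n]) for n in SPECIES_NAMES))


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants and the (isothermal) system temperature.

    Kw is the water ion product in volume units: 1e-8 (mol/m^3)^2 equals the
    familiar 1e-14 (mol/L)^2.
    """

    F: float = 96485.33212  # C/mol
    R: float = 8.314462618  # J/(mol K)
    T: float = 298.15       # K
    Kw: float = 1e-8        # (mol/m^3)^2

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ConfigurationError(f"temperature must be positive, got {self.T}")

    @property
    def RT(self) -> float:
        return self.R * self.T


@dataclass(frozen=True)
class ReactionParams:
    """Rate and equilibrium constants of the two homogeneous reactions.

    k1 (1/s) and k_m1 (m^3/(mol s)) are the forward/backward constants of
    casein deprotonation; their ratio is the acid constant Ka (mol/m^3),
    with pKa = 4.8 on the mol/L scale.  kr is the water recombination
    constant and kd_cH2O the lumped dissociation source kr*Kw, which makes
    pure water a fixed point of the kinetics.

    The printed forward constant of casein deprotonation is inconsistent with
    the stated Ka and k_m1; the default k1 = Ka * k_m1 restores detailed
    balance.  Pass k1 explicitly to experiment with other values.
    """

    k1: float = field(default=10 ** (3 - 4.8) * 1e7)   # 1/s
    k_m1: float = 1e7                                  # m^3/(mol s)
    Ka: float = field(default=10 ** (3 - 4.8))         # mol/m^3
    kr: float = 1e7                                    # m^3/(mol s)
    kd_cH2O: float = field(default=1e7 * 1e-8)         # mol/(m^3 s)

    def __post_init__(self) -> None:
        if min(self.k1, self.k_m1, self.Ka, self.kr) <= 0:
            raise ConfigurationError("all rate constants must be positive")

    @classmethod
    def consistent(
        cls,
        Ka: float = 10 ** (3 - 4.8),
        k_m1: float = 1e7,
        kr: float = 1e7,
        Kw: float = 1e-8,
    ) -> "ReactionParams":
        """Build a detailed-balance-consistent parameter set from Ka and k_m1."""
        return cls(k1=Ka * k_m1, k_m1=k_m1, Ka=Ka, kr=kr, kd_cH2O=kr * Kw)

    def validate_equilibrium(self, Kw: float, rtol: float = 1e-9) -> None:
        """Raise if k1/k_m1 deviates from Ka or kd_cH2O from kr*Kw."""
        if not math.isclose(self.k1 / self.k_m1, self.Ka, rel_tol=rtol):
            raise ConfigurationError(
                f"k1/k_m1 = {self.k1 / self.k_m1:g} inconsistent with Ka = {self.Ka:g}"
            )
        if not math.isclose(self.kd_cH2O, self.kr * Kw, rel_tol=rtol):
            raise ConfigurationError(
                f"kd_cH2O = {self.kd_cH2O:g} inconsistent with kr*Kw = {self.kr * Kw:g}"
            )


def reaction_sources(c: np.ndarray, params: ReactionParams) -> np.ndarray:
    """Homogeneous source terms R_i (mol/(m^3 s)) for every species.

    ``c`` holds concentrations in the canonical order, shape (7,) or (n, 7);
    the result has the same shape.  Na+, K+ and Cl- are inert.  The casein
    reaction rate (rate of HCas0 formation) is

        r_HCas0 = -k1 * c_HCas0 + k_m1 * c_H * c_Cas

    and the water recombination rate r_H2O = kr * c_H * c_OH - kd_cH2O, so

        R_H = -r_HCas0 - r_H2O,  R_OH = -r_H2O,
        R_HCas0 = r_HCas0,       R_Cas = -r_HCas0.
    """
    c = np.asarray(c, dtype=float)
    if c.shape[-1] != 7:
        raise ValueError(f"expected 7 species on the last axis, got shape {c.shape}")
    r1 = -params.k1 * c[..., I_HCAS0] + params.k_m1 * c[..., I_H] * c[..., I_CAS]
    r2 = params.kr * c[..., I_H] * c[..., I_OH] - params.kd_cH2O
    R = np.zeros_like(c)
    R[..., I_H] = -r1 - r2
    R[..., I_OH] = -r2
    R[..., I_CAS] = -r1
    R[..., I_HCAS0] = r1
    return R


def equilibrium_speciation(
    c_total_casein: float, pH: float, Ka: float = 10 ** (3 - 4.8)
) -> tuple[float, float]:
    """Split total casein between Cas- and HCas0 at the given pH.

    Closed-form acid-base equilibrium: with c_H = 10**(3 - pH) mol/m^3,

        c_Cas = c_total * Ka / (Ka + c_H),   c_HCas0 = c_total - c_Cas.

    At pH = pKa = 4.8 the two forms are equal.
    """
    if c_total_casein < 0:
        raise DomainError("total casein concentration must be non-negative")
    c_H = 10.0 ** (3.0 - pH)
    c_cas = c_total_casein * Ka / (Ka + c_H)
    return c_cas, c_total_casein - c_cas


def conductivity(
    c: np.ndarray, species: SpeciesSet, constants: PhysicalConstants
) -> float:
    """Dilute-solution conductivity kappa = (F^2/RT) * sum_i z_i^2 D_i c_i (S/m).

    This is the Nernst-Einstein form of the additive (Kohlrausch) conductivity
    law, with ionic mobilities taken from the diffusivity table; no activity
    corrections are applied.
    """
    c = np.asarray(c, dtype=float)
    return float(
        constants.F**2 / constants.RT * np.dot(species.z**2 * species.D, c)
    )


@dataclass(frozen=True)
class BulkComposition:
    """Electroneutral bulk composition consistent with pH0 and kappa_target.

    ``c0`` is the per-species concentration vector (mol/m^3) in canonical
    order, held fixed at the outer edge of the diffusion boundary layer.
    """

    c0: np.ndarray
    pH0: float
    kappa_target: float

    def __post_init__(self) -> None:
        self.c0.setflags(write=False)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SPECIES_NAMES, map(float, self.c0)))


def build_bulk_composition(
    pH0: float = 6.5,
    c_total_casein: float = 13.0,
    kappa_target: float = 0.31,
    species: SpeciesSet | None = None,
    constants: PhysicalConstants | None = None,
    Ka: float = 10 ** (3 - 4.8),
    hcas0_in_bulk: str = "equilibrium",
) -> BulkComposition:
    """Construct the bulk solution from pH, total casein and conductivity.

    Procedure: H+ and OH- follow from pH0 and Kw; total casein is split by
    :func:`equilibrium_speciation` at pH0 (or kept fully dissociated with
    ``hcas0_in_bulk="zero"``); the supporting KCl concentration (c_K = c_Cl)
    is the unique value for which the total conductivity equals
    ``kappa_target``; Na+ then closes the electroneutrality balance.

    Raises
    ------
    InfeasibleCompositionError
        If kappa_target is below the conductivity of the casein/Na/H/OH
        background, so no non-negative KCl concentration can reach it.
    """
    species = species or build_species_table()
    constants = constants or PhysicalConstants()

    c_H = 10.0 ** (3.0 - pH0)
    c_OH = constants.Kw / c_H
    if hcas0_in_bulk == "equilibrium":
        c_cas, c_hcas0 = equilibrium_speciation(c_total_casein, pH0, Ka)
    elif hcas0_in_bulk == "zero":
        c_cas, c_hcas0 = c_total_casein, 0.0
    else:
        raise ConfigurationError(
            f"hcas0_in_bulk must be 'equilibrium' or 'zero', got {hcas0_in_bulk!r}"
        )

    # Na+ from electroneutrality; KCl (equal K+ and Cl-) cancels in the
    # charge balance, so c_Na is fixed before the conductivity is matched.
    c_na = c_cas + c_OH - c_H
    if c_na < 0:
        raise InfeasibleCompositionError(
            "electroneutrality requires a cation beyond Na+: lower pH0 or raise casein"
        )

    c_bg = np.zeros(7)
    c_bg[[I_NA, I_H, I_OH, I_CAS, I_HCAS0]] = [c_na, c_H, c_OH, c_cas, c_hcas0]
    kappa_bg = conductivity(c_bg, species, constants)
    if kappa_bg > kappa_target:
        raise InfeasibleCompositionError(
            f"background conductivity {kappa_bg:.4g} S/m exceeds target "
            f"{kappa_target:.4g} S/m"
        )
    # kappa is linear in c_KCl, so the root is closed-form.
    fac = constants.F**2 / constants.RT
    c_kcl = (kappa_target - kappa_bg) / (fac * (species.D[I_K] + species.D[I_CL]))

    c0 = c_bg.copy()
    c0[I_K] = c0[I_CL] = c_kcl
    return BulkComposition(c0=c0, pH0=pH0, kappa_target=kappa_target)


def stokes_einstein_diffusivity(
    r: float, T: float = 298.15, eta: float = 8.9e-4
) -> float:
    """Stokes-Einstein diffusivity D = kB*T / (6 pi eta r) of a spherical particle.

    Default temperature and dynamic viscosity correspond to water at 25 C.
    A radius of ~3.7 nm reproduces the caseinate diffusivity in the default
    species table.
    """
    if r <= 0 or eta <= 0 or T <= 0:
        raise DomainError("radius, temperature and viscosity must be positive")
    return _KB * T / (6.0 * math.pi * eta * r)


def ph_of(c_H: float | np.ndarray) -> float | np.ndarray:
    """pH from a hydrogen-ion concentration in mol/m^3: pH = 3 - log10(c_H)."""
    c_H = np.asarray(c_H, dtype=float)
    if np.any(c_H <= 0):
        raise DomainError("c_H must be positive to define pH")
    out = 3.0 - np.log10(c_H)
    return float(out) if out.ndim == 0 else out
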