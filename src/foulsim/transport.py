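"""Finite-volume Nernst-Planck transport in the diffusion boundary layer.

The domain is the stagnant film 0 <= x <= delta between the cation-exchange
face of the bipolar membrane (x = 0) and the well-mixed bulk (x = delta).
Seven species are transported by diffusion and migration,

    j_i = -D_i * (dc_i/dx + z_i c_i (F/RT) dphi/dx),
    dc_i/dt = -dj_i/dx + R_i,

with local electroneutrality (sum z_i c_i = 0).  The electric field is
eliminated analytically: requiring F * sum z_i j_i = i(t) at every position
gives

    dphi/dx = -(RT/F) * (i/F + sum z_i D_i dc_i/dx) / (sum z_i^2 D_i c_i),

so no Poisson equation is solved; phi is recovered afterwards from
phi(0) = 0 for output only.  Boundary conditions: at x = 0 a galvanostatic
proton flux j_H = i*t_H/F, a heterogeneous deposit-exchange flux for HCas0
and zero flux for everything else; at x = delta, Dirichlet bulk values.

Spatial scheme: vertex-centred finite volumes on a uniform grid (half cells
at the walls), central/arithmetic-mean face values for the migration term.
Time integration: method of lines with LSODA (banded Jacobian), restarted at
every current switching instant so each solve sees a smooth right-hand side.
Because the face charge flux equals i(t)/F by construction and the reactions
conserve charge, per-node electroneutrality is a linear invariant of the
semi-discrete system; its drift is monitored as a correctness check, never
enforced.

Two auxiliary states ride along with the 7N concentrations: the deposit
thickness alpha and the time-integrated casein outflow through the last
interior face, which closes the casein mass balance

    integral(c_Cas + c_HCas0) dx + alpha * c0_dep + outflow = const.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import odeint

from . import _kernels, pef
from .chemistry import (
    I_CAS,
    I_H,
    I_HCAS0,
    SPECIES_NAMES,
    BulkComposition,
    PhysicalConstants,
    ReactionParams,
    SpeciesSet,
    build_bulk_composition,
    build_species_table,
    ph_of,
    reaction_sources,
)
from .errors import (
    ConfigurationError,
    IntegrationError,
    SingularFieldError,
    StateError,
)
from .fouling import ACTIVE_AREA_M2, DepositParams, deposit_mass_per_area

__all__ = ["Grid", "SolutionState", "FluxField", "Scenario", "SolverOptions",
           "SimulationResult", "make_grid", "potential_gradient",
           "surface_boundary_fluxes", "compute_fluxes", "rhs", "integrate"]

log = logging.getLogger(__name__)

# Jacobian bandwidth of the node-major state layout
# [alpha, c(node 0, 7 species), ..., c(node N-1), casein_outflow]:
# nearest-neighbour species coupling spans at most 13 indices, alpha couples
# to HCas0 at node 0 (offset 7) and the outflow to the last two nodes (14).
_BANDWIDTH = 14


@dataclass(frozen=True)
class Grid:
    """Uniform 1-D grid over the diffusion boundary layer."""

    delta: float              # m
    N: int
    x: np.ndarray             # node coordinates, x[0] = 0, x[-1] = delta
    faces: np.ndarray         # midpoints between nodes

    def __post_init__(self) -> None:
        self.x.setflags(write=False)
        self.faces.setflags(write=False)

    @property
    def dx(self) -> float:
        return self.delta / (self.N - 1)


def make_grid(delta: float, N: int = 201) -> Grid:
    """Uniform grid with nodes at the membrane surface (0) and bulk edge (delta)."""
    if delta <= 0:
        raise ConfigurationError("delta must be positive")
    if N < 4:
        raise ConfigurationError("need at least 4 grid nodes")
    x = np.linspace(0.0, delta, N)
    return Grid(delta=float(delta), N=int(N), x=x, faces=0.5 * (x[:-1] + x[1:]))


@dataclass
class SolutionState:
    """Concentration fields plus deposit thickness at one instant."""

    t: float
    c: np.ndarray          # (N, 7) mol/m^3, canonical species order
    alpha: float           # m
    casein_outflow: float = 0.0   # mol/m^2 through the last interior face

    def electroneutrality_residual(self, z: np.ndarray) -> float:
        """Max over nodes of |sum z_i c_i| / sum |z_i| c_i (relative)."""
        num = np.abs(self.c @ z)
        den = self.c @ np.abs(z)
        return float(np.max(num / np.maximum(den, 1e-300)))

    def validate(self, species: SpeciesSet, atol: np.ndarray,
                 en_rtol: float = 1e-6) -> None:
        if self.alpha < -1e-15:
            raise StateError(f"negative deposit thickness alpha = {self.alpha:g}")
        floor = -10.0 * atol  # solver-scale tolerance on negativity
        if np.any(self.c < floor):
            worst = float(np.min(self.c / np.maximum(atol, 1e-300)))
            raise StateError(
                f"concentration below -10*atol at t = {self.t:g} s "
                f"(min c/atol = {worst:.1f})"
            )
        res = self.electroneutrality_residual(species.z)
        if res > en_rtol:
            raise StateError(
                f"electroneutrality drift {res:.2e} exceeds {en_rtol:g} at t = {self.t:g}"
            )


@dataclass(frozen=True)
class FluxField:
    """Per-species fluxes and potential gradient at the interior faces."""

    j: np.ndarray          # (N-1, 7) mol/(m^2 s)
    dphi_dx: np.ndarray    # (N-1,) V/m


def potential_gradient(
    c_face: np.ndarray,
    dcdx_face: np.ndarray,
    i: float,
    species: SpeciesSet,
    constants: PhysicalConstants,
) -> np.ndarray:
    """Electric-field term dphi/dx (V/m) from the electroneutral current relation.

    ``c_face`` and ``dcdx_face`` have species on the last axis.  Raises
    :class:`SingularFieldError` where the ionic strength factor
    sum z^2 D c vanishes.
    """
    c_face = np.atleast_2d(np.asarray(c_face, dtype=float))
    dcdx_face = np.atleast_2d(np.asarray(dcdx_face, dtype=float))
    S = c_face @ (species.z**2 * species.D)
    if np.any(S <= 0):
        raise SingularFieldError("vanishing ionic strength at a face")
    numer = i / constants.F + dcdx_face @ (species.z * species.D)
    out = -(constants.RT / constants.F) * numer / S
    return out[0] if out.shape[0] == 1 and np.asarray(c_face).ndim == 2 else out


def compute_fluxes(
    c: np.ndarray,
    grid: Grid,
    i: float,
    species: SpeciesSet,
    constants: PhysicalConstants,
) -> FluxField:
    """Diffusion + migration fluxes at all interior faces (central scheme)."""
    inv_dx = 1.0 / grid.dx
    cf = 0.5 * (c[:-1] + c[1:])
    dcdx = (c[1:] - c[:-1]) * inv_dx
    S = cf @ (species.z**2 * species.D)
    if np.any(S <= 0):
        raise SingularFieldError("vanishing ionic strength at a face")
    numer = i / constants.F + dcdx @ (species.z * species.D)
    dphidx = -(constants.RT / constants.F) * numer / S
    j = (-species.D * dcdx
         - (constants.F / constants.RT * species.D * species.z) * cf * dphidx[:, None])
    return FluxField(j=j, dphi_dx=dphidx)


def surface_boundary_fluxes(
    state: SolutionState,
    i: float,
    deposit: DepositParams,
    constants: PhysicalConstants,
    t_H: float = 1.0,
) -> np.ndarray:
    """Species fluxes at the membrane surface x = 0 (positive toward bulk).

    The whole current enters as protons (j_H = i*t_H/F); neutral casein is
    exchanged with the deposit layer; every other species is blocked, so
    F * sum z_i j_i = i exactly.
    """
    j0 = np.zeros(7)
    j0[I_H] = i * t_H / constants.F
    j0[I_HCAS0] = (deposit.a * state.alpha * deposit.c0_dep
                   - deposit.b * state.c[0, I_HCAS0])
    return j0


@dataclass(frozen=True)
class SolverOptions:
    """Tolerances and limits for the stiff integrator."""

    rtol: float = 1e-6
    atol_scale: float = 1e-12   # atol_i = atol_scale * max(1, c_bulk_i)
    mxstep: int = 2_000_000
    max_retries: int = 2        # tolerance tightenings on invariant violation
    en_rtol: float = 1e-6       # electroneutrality drift allowed before error


@dataclass(frozen=True)
class Scenario:
    """Everything :func:`integrate` needs for one simulation."""

    mode: pef.PEFMode
    grid: Grid
    species: SpeciesSet = field(default_factory=build_species_table)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    reaction: ReactionParams = field(default_factory=ReactionParams)
    deposit: DepositParams = field(default_factory=DepositParams)
    bulk: BulkComposition | None = None
    solver: SolverOptions = field(default_factory=SolverOptions)
    snapshot_times: tuple[float, ...] | None = None   # None -> pef sample times
    series_dt: float = 5.0      # max spacing of time-series records, s

    def resolved_bulk(self) -> BulkComposition:
        return self.bulk if self.bulk is not None else build_bulk_composition(
            species=self.species, constants=self.constants, Ka=self.reaction.Ka
        )


@dataclass
class SimulationResult:
    """Time series, profile snapshots and summary of one run."""

    config: dict
    t: np.ndarray                  # s
    i_applied: np.ndarray          # A/m^2 (left limit at switches)
    alpha: np.ndarray              # m
    mass_per_area: np.ndarray      # mg/cm^2
    ph_surface: np.ndarray
    profiles: dict[float, "np.ndarray"]   # t -> (N, 7) concentrations
    profile_phi: dict[float, np.ndarray]  # t -> (N,) potential, phi(0) = 0
    grid: Grid
    diagnostics: dict

    @property
    def summary(self) -> dict:
        return {
            "final_alpha_m": float(self.alpha[-1]),
            "final_alpha_um": float(self.alpha[-1] * 1e6),
            "final_mass_mg_per_cm2": float(self.mass_per_area[-1]),
            "final_mass_mg": float(self.mass_per_area[-1] * ACTIVE_AREA_M2 * 1e4),
            "min_surface_ph": float(np.min(self.ph_surface)),
        }

    def profile_frame(self, t: float):
        """Profile snapshot at time t as a pandas DataFrame (CSV layout)."""
        import pandas as pd

        c = self.profiles[t]
        cols = {"x_m": self.grid.x}
        for k, name in enumerate(("c_Na", "c_K", "c_H", "c_Cl", "c_OH",
                                  "c_Cas", "c_HCas0")):
            cols[name] = c[:, k]
        cols["pH"] = ph_of(c[:, I_H])
        cols["phi_V"] = self.profile_phi[t]
        return pd.DataFrame(cols)

    def series_frame(self):
        """Time series as a pandas DataFrame (CSV layout)."""
        import pandas as pd

        return pd.DataFrame({
            "t_s": self.t,
            "i_A_per_m2": self.i_applied,
            "alpha_m": self.alpha,
            "mass_mg_per_cm2": self.mass_per_area,
            "pH_surface": self.ph_surface,
        })


class _SemiDiscreteRHS:
    """Vectorised right-hand side of the method-of-lines system.

    State layout: ``y = [alpha, c(node 0), ..., c(node N-1), outflow]`` with
    seven species per node.  The applied current density is piecewise
    constant and fixed per instance; :func:`integrate` swaps it between
    segments.
    """

    def __init__(self, scenario: Scenario, bulk: BulkComposition,
                 use_kernels: bool | None = None):
        g = scenario.grid
        sp = scenario.species
        self.N = g.N
        self.inv_dx = 1.0 / g.dx
        self.D = sp.D
        self.z = sp.z
        self.z2D = sp.z**2 * sp.D
        self.zD = sp.z * sp.D
        self.F = scenario.constants.F
        self.RT_over_F = scenario.constants.RT / scenario.constants.F
        self.F_over_RT_Dz = scenario.constants.F / scenario.constants.RT * sp.D * sp.z
        self.reaction = scenario.reaction
        self.dep = scenario.deposit
        self.t_H = scenario.mode.t_H
        self.i_current = 0.0
        self.c_bulk = bulk.c0
        self.use_kernels = _kernels.HAVE_NUMBA if use_kernels is None else use_kernels

    def _kernel_args(self) -> tuple:
        p, d = self.reaction, self.dep
        return (self.N, self.inv_dx, self.D, self.z2D, self.zD,
                self.F_over_RT_Dz, self.F, self.RT_over_F,
                p.k1, p.k_m1, p.kr, p.kd_cH2O, d.a, d.b, d.c0_dep, self.t_H)

    def initial_state(self) -> np.ndarray:
        y0 = np.empty(7 * self.N + 2)
        y0[0] = 0.0
        y0[1:-1] = np.tile(self.c_bulk, self.N)
        y0[-1] = 0.0
        return y0

    def banded_jacobian(self, t: float, y: np.ndarray) -> np.ndarray:
        """Analytic Jacobian in LAPACK banded storage (ml = mu = 14).

        Entry (i, j) of the dense Jacobian lives at ``band[mu + i - j, j]``.
        With the node-major layout every inter-node block sits on a fixed
        band row per (species, species', node-offset) triple, so assembly is
        147 vectorised scatters.  Supplying this to LSODA removes the ~29
        right-hand-side evaluations per finite-difference Jacobian update,
        the dominant cost of the stiff solve.
        """
        if self.use_kernels:
            return _kernels.jac_kernel(y, self.i_current, *self._kernel_args())
        N, inv_dx, mu = self.N, self.inv_dx, _BANDWIDTH
        n = 7 * N + 2
        band = np.zeros((2 * mu + 1, n))
        alpha = y[0]
        c = y[1:-1].reshape(N, 7)

        cf = 0.5 * (c[:-1] + c[1:])
        dcdx = (c[1:] - c[:-1]) * inv_dx
        S = cf @ self.z2D
        G = self.i_current / self.F + dcdx @ self.zD
        dphidx = -self.RT_over_F * G / S
        A = self.F_over_RT_Dz          # (7,)  per-species migration factor

        invS = 1.0 / S
        # d(dphidx)/dc at the left/right node of each face, shape (N-1, 7)
        base = -dphidx[:, None] * (0.5 * self.z2D) * invS[:, None]
        dphi_L = self.RT_over_F * self.zD * (inv_dx * invS)[:, None] + base
        dphi_R = -self.RT_over_F * self.zD * (inv_dx * invS)[:, None] + base

        eye = np.eye(7)
        diffu = self.D[:, None] * eye * inv_dx                  # (7, 7)
        mig_diag = 0.5 * A[:, None] * eye                       # (7, 7)
        # dj[f, s, s'] for the left and right parent nodes of face f
        Acf = A[None, :, None] * cf[:, :, None]                 # (N-1, 7, 1)
        djL = (diffu[None] - mig_diag[None] * dphidx[:, None, None]
               - Acf * dphi_L[:, None, :])
        djR = (-diffu[None] - mig_diag[None] * dphidx[:, None, None]
               - Acf * dphi_R[:, None, :])

        # reaction Jacobians per node (nodes 0..N-2), shape (N, 7, 7)
        p = self.reaction
        dR = np.zeros((N, 7, 7))
        dr1_h = -p.k1
        dr1_H = p.k_m1 * c[:, I_CAS]
        dr1_C = p.k_m1 * c[:, I_H]
        dr2_H = p.kr * c[:, 4]
        dr2_O = p.kr * c[:, I_H]
        dR[:, I_H, I_H] = -dr1_H - dr2_H
        dR[:, I_H, I_CAS] = -dr1_C
        dR[:, I_H, I_HCAS0] = -dr1_h
        dR[:, I_H, 4] = -dr2_O
        dR[:, 4, I_H] = -dr2_H
        dR[:, 4, 4] = -dr2_O
        dR[:, I_CAS, I_H] = -dr1_H
        dR[:, I_CAS, I_CAS] = -dr1_C
        dR[:, I_CAS, I_HCAS0] = -dr1_h
        dR[:, I_HCAS0, I_H] = dr1_H
        dR[:, I_HCAS0, I_CAS] = dr1_C
        dR[:, I_HCAS0, I_HCAS0] = dr1_h
        dR[-1] = 0.0

        # block derivatives of the concentration equations
        B_m1 = np.zeros((N, 7, 7))      # d f_k / d c_{k-1}
        B_0 = np.zeros((N, 7, 7))       # d f_k / d c_k
        B_p1 = np.zeros((N, 7, 7))      # d f_k / d c_{k+1}
        B_m1[1:-1] = djL[:-1] * inv_dx
        B_0[1:-1] = (djR[:-1] - djL[1:]) * inv_dx + dR[1:-1]
        B_p1[1:-1] = -djR[1:] * inv_dx
        # surface node (half cell): f_0 = (j_surf - j_0) * 2/dx + R_0
        B_0[0] = -djL[0] * (2.0 * inv_dx) + dR[0]
        B_0[0, I_HCAS0, I_HCAS0] += -self.dep.b * (2.0 * inv_dx)
        B_p1[0] = -djR[0] * (2.0 * inv_dx)
        # bulk Dirichlet node: zero rows (already zero)

        cols = 1 + 7 * np.arange(N)
        for s in range(7):
            for sp in range(7):
                # same-node block: i = 1+7k+s, j = 1+7k+sp
                band[mu + s - sp, cols + sp] += B_0[:, s, sp]
                # left-neighbour block: j = 1+7(k-1)+sp
                band[mu + s - sp + 7, cols[:-1] + sp] += B_m1[1:, s, sp]
                # right-neighbour block: j = 1+7(k+1)+sp
                band[mu + s - sp - 7, cols[1:] + sp] += B_p1[:-1, s, sp]

        # deposit thickness row and its couplings
        band[mu, 0] = -self.dep.a                                   # d f_a/d a
        band[mu - 7, 1 + I_HCAS0] = self.dep.b / self.dep.c0_dep    # d f_a/d c
        band[mu + 7, 0] = (self.dep.a * self.dep.c0_dep             # d f_0/d a
                           * 2.0 * inv_dx)
        # cumulative casein outflow row: d f_J / d c at the last face
        iJ = n - 1
        for sp in range(7):
            jL = 1 + 7 * (N - 2) + sp
            jR = 1 + 7 * (N - 1) + sp
            band[mu + iJ - jL, jL] = djL[-1, I_CAS, sp] + djL[-1, I_HCAS0, sp]
            band[mu + iJ - jR, jR] = djR[-1, I_CAS, sp] + djR[-1, I_HCAS0, sp]
        return band

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        if self.use_kernels:
            return _kernels.rhs_kernel(y, self.i_current, *self._kernel_args())
        N, inv_dx = self.N, self.inv_dx
        alpha = y[0]
        c = y[1:-1].reshape(N, 7)
        dy = np.empty_like(y)
        dc = dy[1:-1].reshape(N, 7)

        cf = 0.5 * (c[:-1] + c[1:])
        dcdx = (c[1:] - c[:-1]) * inv_dx
        S = cf @ self.z2D
        dphidx = -self.RT_over_F * (self.i_current / self.F + dcdx @ self.zD) / S
        j = -self.D * dcdx - self.F_over_RT_Dz * cf * dphidx[:, None]

        p = self.reaction
        r1 = -p.k1 * c[:, I_HCAS0] + p.k_m1 * c[:, I_H] * c[:, I_CAS]
        r2 = p.kr * c[:, I_H] * c[:, 4] - p.kd_cH2O   # c[:, I_OH]

        dc[1:-1] = (j[:-1] - j[1:]) * inv_dx
        surf_hcas0 = self.dep.a * alpha * self.dep.c0_dep - self.dep.b * c[0, I_HCAS0]
        dc[0] = -j[0] * (2.0 * inv_dx)
        dc[0, I_H] += (self.i_current * self.t_H / self.F) * (2.0 * inv_dx)
        dc[0, I_HCAS0] += surf_hcas0 * (2.0 * inv_dx)
        # reaction sources (inert: Na, K, Cl)
        dc[:-1, I_H] += -r1[:-1] - r2[:-1]
        dc[:-1, 4] += -r2[:-1]
        dc[:-1, I_CAS] += -r1[:-1]
        dc[:-1, I_HCAS0] += r1[:-1]
        dc[-1] = 0.0   # Dirichlet bulk node

        dy[0] = -self.dep.a * alpha + self.dep.b * c[0, I_HCAS0] / self.dep.c0_dep
        dy[-1] = j[-1, I_CAS] + j[-1, I_HCAS0]
        return dy


def rhs(state: SolutionState, t: float, scenario: Scenario) -> tuple[np.ndarray, float]:
    """Time derivatives (dc/dt as (N, 7), dalpha/dt) at one state.

    Convenience wrapper around the packed semi-discrete right-hand side used
    by the integrator; the applied current is ``waveform(mode, t)``.
    """
    bulk = scenario.resolved_bulk()
    f = _SemiDiscreteRHS(scenario, bulk)
    f.i_current = pef.waveform(scenario.mode, t)
    y = np.empty(7 * scenario.grid.N + 2)
    y[0] = state.alpha
    y[1:-1] = state.c.ravel()
    y[-1] = state.casein_outflow
    dy = f(t, y)
    return dy[1:-1].reshape(scenario.grid.N, 7).copy(), float(dy[0])


def _recover_phi(c: np.ndarray, grid: Grid, i: float, species: SpeciesSet,
                 constants: PhysicalConstants) -> np.ndarray:
    """Potential profile from phi(0) = 0 by integrating the face gradients."""
    flux = compute_fluxes(c, grid, i, species, constants)
    phi = np.empty(grid.N)
    phi[0] = 0.0
    np.cumsum(flux.dphi_dx * grid.dx, out=phi[1:])
    return phi


def integrate(
    scenario: Scenario,
    progress: Callable[[int, int, float], None] | None = None,
) -> SimulationResult:
    """Advance the coupled transport/deposit system over the full process.

    Starts from the uniform bulk composition with a clean membrane
    (alpha = 0) and integrates segment by segment between current switching
    instants, so the stiff solver never steps across a discontinuity of
    i(t).  Solution invariants (non-negativity, electroneutrality) are
    checked at every recorded time; a violation triggers a retry of the
    segment with a tenfold tighter relative tolerance before giving up.

    ``progress``, if given, is called as ``progress(segment, n_segments, t)``
    after each segment.
    """
    mode = scenario.mode
    grid = scenario.grid
    bulk = scenario.resolved_bulk()
    f = _SemiDiscreteRHS(scenario, bulk)

    sw = pef.switching_times(mode)
    total = sw[-1]
    snap_times = (scenario.snapshot_times if scenario.snapshot_times is not None
                  else (0.0,) + pef.sample_times(mode) + (total,))
    snap_times = tuple(sorted({float(t) for t in snap_times if 0.0 <= t <= total}))

    atol = np.empty(7 * grid.N + 2)
    atol[0] = 1e-12                      # alpha, m
    atol[-1] = 1e-9                      # cumulative outflow, mol/m^2
    atol[1:-1] = np.tile(scenario.solver.atol_scale * np.maximum(1.0, bulk.c0),
                         grid.N)

    y = f.initial_state()
    rec_t: list[float] = [0.0]
    rec_i: list[float] = [pef.waveform(mode, 0.0)]
    rec_alpha: list[float] = [0.0]
    rec_ph: list[float] = [ph_of(bulk.c0[I_H])]
    profiles: dict[float, np.ndarray] = {}
    profile_phi: dict[float, np.ndarray] = {}
    max_en_drift = 0.0

    def record(t: float, yv: np.ndarray, i_cur: float, want_profile: bool) -> None:
        nonlocal max_en_drift
        state = SolutionState(t=t, c=yv[1:-1].reshape(grid.N, 7), alpha=yv[0],
                              casein_outflow=yv[-1])
        state.validate(scenario.species, atol[1:-1].reshape(grid.N, 7)[0],
                       scenario.solver.en_rtol)
        max_en_drift = max(max_en_drift,
                           state.electroneutrality_residual(scenario.species.z))
        rec_t.append(t)
        rec_i.append(i_cur)
        rec_alpha.append(float(yv[0]))
        rec_ph.append(float(ph_of(max(state.c[0, I_H], 1e-300))))
        if want_profile:
            profiles[t] = state.c.copy()
            profile_phi[t] = _recover_phi(state.c, grid, i_cur,
                                          scenario.species, scenario.constants)
    if 0.0 in snap_times:
        profiles[0.0] = y[1:-1].reshape(grid.N, 7).copy()
        profile_phi[0.0] = _recover_phi(profiles[0.0], grid, rec_i[0],
                                        scenario.species, scenario.constants)

    n_seg = len(sw) - 1
    for k in range(n_seg):
        t0, t1 = sw[k], sw[k + 1]
        i_cur = float(pef.waveform(mode, 0.5 * (t0 + t1)))
        f.i_current = i_cur
        inner_snaps = [t for t in snap_times if t0 < t <= t1]
        n_series = max(1, int(np.ceil((t1 - t0) / scenario.series_dt)))
        ts = np.unique(np.concatenate([
            np.linspace(t0, t1, n_series + 1), np.asarray(inner_snaps, dtype=float)
        ]))

        rtol = scenario.solver.rtol
        for attempt in range(scenario.solver.max_retries + 1):
            out, info = odeint(
                f, y, ts, tfirst=True, ml=_BANDWIDTH, mu=_BANDWIDTH,
                Dfun=f.banded_jacobian,
                rtol=rtol, atol=atol, mxstep=scenario.solver.mxstep,
                full_output=True,
            )
            if info["message"] != "Integration successful.":
                raise IntegrationError(
                    f"segment [{t0:g}, {t1:g}] s failed: {info['message']}"
                )
            try:
                for row, t in zip(out[1:], ts[1:]):
                    record(float(t), row, i_cur, float(t) in inner_snaps)
                break
            except StateError:
                if attempt == scenario.solver.max_retries:
                    raise
                # drop the partial records of this segment and retry tighter
                keep = len([t for t in rec_t if t <= t0])
                del rec_t[keep:], rec_i[keep:], rec_alpha[keep:], rec_ph[keep:]
                for t in list(profiles):
                    if t > t0:
                        del profiles[t], profile_phi[t]
                rtol *= 0.1
                log.warning("retrying segment [%g, %g] s with rtol = %g",
                            t0, t1, rtol)
        y = out[-1]
        if progress is not None:
            progress(k + 1, n_seg, float(t1))

    alpha_arr = np.asarray(rec_alpha)
    dep_rho = scenario.deposit.rho
    result = SimulationResult(
        config={"mode": mode.name, "tau_on": mode.tau_on, "tau_off": mode.tau_off,
                "i_pulse": mode.i_pulse, "delta_m": grid.delta, "N": grid.N},
        t=np.asarray(rec_t),
        i_applied=np.asarray(rec_i),
        alpha=alpha_arr,
        mass_per_area=np.array([deposit_mass_per_area(a, dep_rho)
                                for a in alpha_arr]),
        ph_surface=np.asarray(rec_ph),
        profiles=profiles,
        profile_phi=profile_phi,
        grid=grid,
        diagnostics={
            "max_electroneutrality_drift": max_en_drift,
            "final_casein_outflow_mol_per_m2": float(y[-1]),
            "n_segments": n_seg,
        },
    )
    return result


def casein_inventory(result_c: np.ndarray, alpha: float, grid: Grid,
                     c0_dep: float) -> float:
    """Total casein per membrane area (mol/m^2): solution integral + deposit.

    Uses the finite-volume quadrature matching the scheme (half cells at the
    walls, bulk node excluded as the Dirichlet reservoir).
    """
    w = np.full(grid.N, grid.dx)
    w[0] = 0.5 * grid.dx
    w[-1] = 0.0
    w[-2] = 1.0 * grid.dx  # last interior node keeps a full cell
    total = float(w @ (result_c[:, I_CAS] + result_c[:, I_HCAS0]))
    return total + alpha * c0_dep
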