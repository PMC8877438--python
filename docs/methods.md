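# Methods

## Model

The simulator solves an electroneutral Nernst–Planck reaction–transport
system over the diffusion boundary layer (DBL) adjacent to the
cation-exchange face of a bipolar membrane, coupled to a single-state
deposit-layer ODE.  The physical picture: water splitting inside the bipolar
membrane injects protons into the DBL; the local pH drops from the bulk
value of 6.5 toward 2.5–2.8 at the surface under current; caseinate anions
(Cas⁻) protonate to neutral, insoluble casein (HCas⁰) near the proton
front; HCas⁰ attaches to the membrane as a loose film of thickness α and
redissolves when the pause of a pulsed schedule lets the pH recover.

Assumptions inherited from the problem formulation:

* one-dimensional stagnant film; hydrodynamics enter only through the DBL
  thickness δ (Re 187/374/560 ↦ 60/40/30 µm);
* local electroneutrality (no space charge, no Poisson equation); the
  electric field follows from the condition that F·Σzⱼjⱼ equals the applied
  current density at every position, and φ is recovered for output only by
  integrating from φ(0) = 0;
* the membrane passes only protons (transport number t_H = 1, galvanostatic
  boundary j_H(0) = i·t_H/F); all other ions are blocked at x = 0;
* Dirichlet bulk values at x = δ, constant in time (well-mixed reservoir);
* the deposit has no transport resistance and does not shrink the DBL; it
  couples to the solution only through the surface exchange flux;
* isothermal, dilute-solution transport (no activity corrections).

## Parameters

| symbol | value | units | meaning / rationale |
|---|---|---|---|
| δ | 60, 40, 30 | µm | DBL thickness per Reynolds number 187/374/560 |
| i_pulse | 50 | A/m² | pulse current density (5 mA/cm²) |
| D(Na⁺,K⁺,H⁺,Cl⁻,OH⁻) | 1.33/1.98/9.3/2.03/5.27 ×10⁻⁹ | m²/s | infinite-dilution values |
| D(Cas⁻) | 6.6×10⁻¹¹ | m²/s | Stokes–Einstein, r ≈ 3.7 nm at 25 °C, η = 8.9×10⁻⁴ Pa·s |
| D(HCas⁰) | 1×10⁻¹² | m²/s | aggregated neutral form; the deposit thickens as this drops |
| Kₐ | 10⁻¹·⁸ ≈ 0.0158 | mol/m³ | casein protonation equilibrium (pKₐ 4.8 on the mol/L scale) |
| k₋₁ | 1×10⁷ | m³/(mol·s) | diffusion-limited recombination |
| k₁ | Kₐ·k₋₁ ≈ 1.58×10⁵ | 1/s | forward rate; fixed by detailed balance (see below) |
| k_r, k_d·c_H₂O | 1×10⁷, k_r·K_w = 0.1 | m³/(mol·s), mol/(m³·s) | water recombination; the lumped dissociation source makes pure water a fixed point |
| a | 1 | 1/s | deposit dissolution rate |
| b | 5×10⁻⁴ | m/s | deposit formation rate |
| ρ, M | 1100 kg/m³, 2.062 kg/mol | — | deposit density and casein molar mass; c⁰ = ρ/M ≈ 533.5 mol/m³ |
| pH⁰, c_casein, κ⁰ | 6.5, 13 mol/m³, 0.31 S/m | — | bulk state of the model feed |

**The forward rate k₁.**  The three constants Kₐ, k₁, k₋₁ of the casein
reaction are over-determined, and the value 1.58 s⁻¹ sometimes quoted for
k₁ is inconsistent with Kₐ = k₁/k₋₁ by five orders of magnitude.  We default
to the detailed-balance-consistent k₁ = Kₐ·k₋₁.  This is not merely a
thermodynamic nicety: with k₁ = 1.58 s⁻¹ the effective equilibrium constant
(1.58×10⁻⁷ mol/m³) drives essentially *all* dissolved casein neutral at any
pH below ~9.8, the pause-end surface pH relaxes to the bulk value, and
deposits stay sub-micron — qualitatively wrong behaviour for this system.
Both choices remain available through the `reaction` configuration block.

**Bulk composition.**  Constructed, not measured: H⁺/OH⁻ from pH 6.5 and
K_w; casein split by the protonation equilibrium at pH 6.5 (Cas⁻ ≈ 12.75,
HCas⁰ ≈ 0.25 mol/m³; a fully-dissociated variant is available); the
supporting KCl set so the Nernst–Einstein conductivity
κ = (F²/RT)·Σzᵢ²Dᵢcᵢ hits 0.31 S/m (c_KCl ≈ 16.1 mol/m³); Na⁺ closes
electroneutrality (≈ 12.75 mol/m³).  No activity corrections — consistent
with the dilute-solution flux law used in transport.

## Numerical scheme

* **Space:** vertex-centred finite volumes on a uniform grid, nodes at
  x = 0 and x = δ (half cells at the walls), N = 201 by default; arithmetic
  face means for the migration term (face Péclet numbers are small).
  Surface pH at end-of-pulse moves by < 0.02 units between N = 201 and 401.
* **Time:** method of lines with LSODA (adaptive, stiff/non-stiff
  switching), rtol 10⁻⁶, per-species atol 10⁻¹²·max(1, c_bulk).  The
  integrator restarts at every pulse/pause switching instant so each solve
  sees a smooth right-hand side.
* **Jacobian:** analytic, banded (bandwidth 14 in the node-major state
  layout `[α, c(node 0), …, c(node N−1), outflow]`), assembled either as
  vectorised numpy or as numba kernels; the two paths agree to machine
  precision and the analytic band is validated against finite differences.
* **Conservation by construction:** the face charge flux equals i(t)/F
  identically (the field is eliminated through exactly that constraint) and
  reaction sources conserve charge, so per-node electroneutrality is a
  linear invariant of the semi-discrete system; its drift (~10⁻¹⁰ relative
  in practice) is monitored as a correctness signal, never corrected.  An
  auxiliary quadrature state accumulates the casein outflow through the last
  interior face, closing the casein balance (solution + deposit + outflow)
  to ≤ 10⁻⁶ relative over full runs.
* **Negativity policy:** concentrations are never clipped; states recorded
  below −10·atol trigger a retry of the segment at tenfold tighter rtol
  (twice, then an error).
* **Stiffness:** the recombination rates (k₋₁·c_H up to ~10⁷ s⁻¹) put the
  reaction eigenvalues far beyond any explicit step; the independent
  cross-check therefore runs an explicitly written fixed-step RK4 reference
  on a reduced problem (δ = 10 µm, N = 21, one pulse/pause cycle) with the
  kinetics slowed to k₋₁ = k_r = 10³ m³/(mol·s) at fixed equilibrium
  constants — preserving every transport term — and agrees with the
  production path to better than 0.1%.

## Test problem sizes

Unit and property tests run on small grids (N = 21–41) and shortened
schedules (tens of seconds); the grid-convergence check uses 100 s of
continuous current; the acceptance suite runs the full-length production
scenarios (up to 10 800 s of process time at N = 201), each simulated once
per session and shared across tests.

## Design choices that were genuinely open

* **Bulk HCas⁰:** the Dirichlet value at x = δ is the pH-6.5 equilibrium
  concentration (≈ 0.25 mol/m³) rather than zero; both are tiny, the choice
  is exposed as `hcas0_in_bulk`.
* **Profile sample times:** canonical snapshots sit ε = 0.4 s before the
  switching instants of the final full period, avoiding evaluation exactly
  at a current discontinuity.
* **α is integrated with the PDE state** (not operator-split), so the
  surface exchange flux and the growth law are consistent within every
  implicit step.
* **Electroneutrality is monitored, not enforced:** boundary fluxes and
  sources are exactly charge-consistent, so drift is pure integration error
  and serves as a built-in diagnostic.

## Known limitations

* The casein "trap" (electromigration/diffusion of Cas⁻ into the layer,
  conversion to slow-diffusing HCas⁰) has no intrinsic cap in this
  formulation: HCas⁰ can reach hundreds of mol/m³ mid-layer under continuous
  current, and the absolute deposit thickness is correspondingly sensitive
  to D(HCas⁰) and to the bulk boundary treatment.  Pulse/pause *orderings*
  (longer pause ⇒ thinner deposit) are robust; absolute thicknesses are not.
* Because a thinner DBL steepens the Cas⁻ depletion gradient, the model can
  yield slightly *more* fouling at higher Reynolds number at fixed mode —
  the flow-rate benefit seen experimentally is not always reproduced, as
  convective wash-off enters only through the lumped coefficient a.
* In-pause deposit dissolution is driven by the surface HCas⁰ pool, which
  the instantaneous protonation equilibrium keeps high while the surface pH
  sits near pKₐ; early cycles can therefore grow the film during pauses as
  well as pulses.
* The positively charged casein form and the dense electrostatically bound
  first layer are not modelled (the only deposit state is α); neither are
  casein micelles, multivalent minerals, activity corrections, or
  membrane-interior transport.
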