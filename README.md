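# foulsim

A one-dimensional, non-stationary simulator of protein (casein) fouling on
the cation-exchange face of a bipolar membrane during electrodialytic
acidification of a sodium caseinate solution, including pulsed-electric-field
(PEF) operation.

## Who this is for

Electromembrane-process researchers and engineers who want to explore how
the galvanostatic pulse/pause schedule and the hydrodynamics (through the
diffusion-boundary-layer thickness) shape concentration polarisation,
surface pH and the growth of the loose casein deposit — without running the
wet experiment.

## The model

The domain is the stagnant diffusion boundary layer (DBL) 0 ≤ x ≤ δ between
the membrane surface (x = 0) and the well-mixed bulk (x = δ).  Seven species
(Na⁺, K⁺, H⁺, Cl⁻, OH⁻, the caseinate anion Cas⁻, and neutral casein HCas⁰)
obey the Nernst–Planck flux law and a material balance with reaction
sources,

    jᵢ = −Dᵢ (∂cᵢ/∂x + zᵢ cᵢ (F/RT) ∂φ/∂x),     ∂cᵢ/∂t = −∂jᵢ/∂x + Rᵢ,

closed by local electroneutrality Σ zᵢcᵢ = 0.  Imposing that the charge flux
equals the applied current density i(t) at every position eliminates the
electric field analytically:

    ∂φ/∂x = −(RT/F) · (i/F + Σ zᵢDᵢ ∂cᵢ/∂x) / (Σ zᵢ²Dᵢcᵢ).

Two homogeneous reactions couple the species: casein protonation
HCas⁰ ⇌ H⁺ + Cas⁻ (pKₐ 4.8) and water recombination H⁺ + OH⁻ ⇌ H₂O.
At the membrane the whole current enters as protons (j_H = i·t_H/F, t_H = 1,
galvanostatic water-splitting boundary), every other ion is blocked, and
neutral casein exchanges with a surface deposit layer of thickness α:

    dα/dt = −a·α + (b/c⁰) · c_HCas⁰(0),       j_HCas⁰(0) = a·α·c⁰ − b·c_HCas⁰(0),

with c⁰ = ρ/M the molar concentration of the condensed casein phase
(ρ = 1.1 g/cm³, M = 2062 g/mol).  Pulsed modes "10–τ" apply 50 A/m² for 10 s
then rest for τ ∈ {10, 20, 33, 50} s, repeated until the charge of a 30-min
continuous run has passed (total durations 60/90/129/180 min).
Hydrodynamics enter through δ only: Re 187/374/560 ↦ δ = 60/40/30 µm.

Numerics: vertex-centred finite volumes (N = 201 nodes by default), method
of lines with LSODA, an analytic banded Jacobian, and integrator restarts at
every current switching instant.  Per-node electroneutrality and the total
casein balance (solution + deposit + boundary outflow) are conserved by
construction and monitored to ≤ 1e−6 relative.

## Worked example

```sh
python examples/cc_concentration_polarization.py
```

prints (continuous current, 50 A/m², δ = 60 µm, 1800 s):

```
  surface pH                 : 2.54
  HCas0 at the membrane      : 45.9 mol/m^3
  HCas0 peak                 : 311.3 mol/m^3 at x = 37.8 um
  Cas- at the membrane       : 0.252 mol/m^3 (bulk: 12.75)
  deposit thickness alpha    : 43.0 um
  deposit mass per area      : 4.73 mg/cm^2
```

Protons injected at the membrane acidify the layer (surface pH 2.54 matches
the film estimate i·δ/(F·D_H)); caseinate flowing in from the bulk converts
to neutral casein where it meets the proton front, piling up in the
bulk-side half of the layer; the surface concentration sets the quasi-steady
deposit film.  The other examples cover speciation vs pH, the pulse
schedules, and cycle-by-cycle deposit kinetics under PEF.

A thin CLI wraps the same library:

```sh
foulsim run --mode 10-50 --re 560 --out out/       # one scenario, CSV outputs
foulsim grid --out out/                            # all 13 scenarios + summary
foulsim speciation --ph 4.8                        # chemistry utility
```

Scenario files (YAML) can override every physical parameter; outputs are
`timeseries.csv`, `profile_<t>.csv`, `summary.csv` and `config_echo.yaml`
per scenario directory.

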