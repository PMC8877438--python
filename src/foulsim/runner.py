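"""Scenario configuration, the standard experiment grid, summaries and file I/O.

The study grid crosses the four pulsed modes (10-10, 10-20, 10-33, 10-50 s)
with three hydrodynamic conditions given as Reynolds numbers.  Hydrodynamics
enter the 1-D model only through the diffusion-boundary-layer thickness:
Re 187 -> 60 um, Re 374 -> 40 um, Re 560 -> 30 um.  A continuous-current
reference at 60 um completes the grid.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pef, transport
from .chemistry import (
    PhysicalConstants,
    ReactionParams,
    build_bulk_composition,
    build_species_table,
)
from .errors import ConfigurationError
from .fouling import DepositParams
from .transport import Scenario, SimulationResult, SolverOptions, make_grid

__all__ = ["RE_TO_DELTA", "ScenarioConfig", "run_scenario", "paper_grid",
           "summarize", "SimulationResult"]

log = logging.getLogger(__name__)

#: Reynolds number -> diffusion-boundary-layer thickness (m).
RE_TO_DELTA = {187: 60e-6, 374: 40e-6, 560: 30e-6}


@dataclass
class ScenarioConfig:
    """User-facing configuration of one simulation.

    Either ``re`` (one of 187/374/560) or an explicit ``delta`` in metres
    must be given.  Every physical parameter can be overridden through the
    nested dictionaries, e.g. ``reaction={"k1": 1.58}`` or
    ``deposit={"b": 1e-3}``.  The model is fully deterministic.
    """

    mode: str = "10-10"
    re: int | None = None
    delta: float | None = None
    N: int = 201
    i_pulse: float = 50.0
    equivalent_on_time: float = 1800.0
    t_H: float = 1.0
    rtol: float = 1e-6
    atol_scale: float = 1e-12
    series_dt: float = 5.0
    snapshot_times: list[float] | None = None
    hcas0_in_bulk: str = "equilibrium"
    chemistry: dict = field(default_factory=dict)   # pH0, c_total_casein, kappa_target, Ka
    reaction: dict = field(default_factory=dict)    # k1, k_m1, kr
    deposit: dict = field(default_factory=dict)     # a, b, rho, M
    constants: dict = field(default_factory=dict)   # F, R, T, Kw
    diffusivity_overrides: dict = field(default_factory=dict)  # name -> D
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved_delta(self) -> float:
        if self.delta is not None:
            if self.delta <= 0:
                raise ConfigurationError("delta must be positive")
            return float(self.delta)
        if self.re is None:
            raise ConfigurationError("give either re or delta")
        try:
            return RE_TO_DELTA[int(self.re)]
        except KeyError:
            raise ConfigurationError(
                f"re must be one of {sorted(RE_TO_DELTA)}, got {self.re}"
            ) from None

    def build(self) -> Scenario:
        """Assemble the transport-level scenario from this configuration."""
        constants = PhysicalConstants(**self.constants)
        overrides = None
        if self.diffusivity_overrides:
            table = build_species_table()
            overrides = {name: (table[name].z, D)
                         for name, D in self.diffusivity_overrides.items()}
        species = build_species_table(overrides)

        rx = dict(self.reaction)
        if "k1" in rx:
            # explicit k1: keep it, recompute Ka for consistency
            k_m1 = rx.get("k_m1", 1e7)
            kr = rx.get("kr", 1e7)
            reaction = ReactionParams(k1=rx["k1"], k_m1=k_m1,
                                      Ka=rx["k1"] / k_m1, kr=kr,
                                      kd_cH2O=kr * constants.Kw)
        else:
            reaction = ReactionParams.consistent(
                Ka=rx.get("Ka", 10 ** (3 - 4.8)), k_m1=rx.get("k_m1", 1e7),
                kr=rx.get("kr", 1e7), Kw=constants.Kw)

        deposit = DepositParams.make(**self.deposit)
        bulk = build_bulk_composition(
            pH0=self.chemistry.get("pH0", 6.5),
            c_total_casein=self.chemistry.get("c_total_casein", 13.0),
            kappa_target=self.chemistry.get("kappa_target", 0.31),
            species=species, constants=constants, Ka=reaction.Ka,
            hcas0_in_bulk=self.hcas0_in_bulk,
        )
        mode = pef.mode_from_name(
            self.mode, i_pulse=self.i_pulse, t_H=self.t_H,
            equivalent_on_time=self.equivalent_on_time,
        )
        return Scenario(
            mode=mode,
            grid=make_grid(self.resolved_delta(), self.N),
            species=species, constants=constants, reaction=reaction,
            deposit=deposit, bulk=bulk,
            solver=SolverOptions(rtol=self.rtol, atol_scale=self.atol_scale),
            snapshot_times=(tuple(self.snapshot_times)
                            if self.snapshot_times is not None else None),
            series_dt=self.series_dt,
        )


def _write_outputs(config: ScenarioConfig, result: SimulationResult,
                   outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.series_frame().to_csv(outdir / "timeseries.csv", index=False)
    for t in result.profiles:
        result.profile_frame(t).to_csv(outdir / f"profile_{t:g}.csv", index=False)
    pd.DataFrame([result.summary]).to_csv(outdir / "summary.csv", index=False)
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def run_scenario(config: ScenarioConfig) -> SimulationResult:
    """Run one configured simulation, optionally writing its output files.

    Progress is logged per ~10% of segments at INFO level on the standard
    logging hierarchy (the CLI wires this to standard error).
    """
    scenario = config.build()
    n_total = len(pef.switching_times(scenario.mode)) - 1
    every = max(1, n_total // 10)

    def progress(k: int, n: int, t: float) -> None:
        if k % every == 0 or k == n:
            log.info("%s delta=%.0fum: segment %d/%d (t = %.1f s)",
                     config.mode, scenario.grid.delta * 1e6, k, n, t)

    result = transport.integrate(scenario, progress=progress)
    result.config.update({"re": config.re, "outdir": config.outdir})
    if config.outdir is not None:
        _write_outputs(config, result, Path(config.outdir))
    return result


def paper_grid(N: int = 201, outdir: str | None = None) -> list[ScenarioConfig]:
    """The 13 standard scenarios: 4 pulsed modes x 3 Reynolds numbers + CC.

    The continuous-current reference runs at delta = 60 um.
    """
    configs = []
    for mode in ("10-10", "10-20", "10-33", "10-50"):
        for re in sorted(RE_TO_DELTA):
            sub = f"{mode}_Re{re}" if outdir else None
            configs.append(ScenarioConfig(
                mode=mode, re=re, N=N,
                outdir=str(Path(outdir) / sub) if outdir else None))
    configs.append(ScenarioConfig(
        mode="cc", delta=60e-6, N=N,
        outdir=str(Path(outdir) / "cc_delta60um") if outdir else None))
    return configs


def summarize(results: list[tuple[ScenarioConfig, SimulationResult]]) -> pd.DataFrame:
    """Tabulate final deposit thickness/mass with change vs the worst case.

    The reference row is (10-10, Re 187); percent change is
    100 * (value/reference - 1), so the reference row shows 0 and more
    favourable conditions show negative values.  Without the reference
    scenario only absolute values are reported (with a warning).
    """
    if not results:
        raise ConfigurationError("summarize needs at least one result")
    rows = []
    for cfg, res in results:
        s = res.summary
        rows.append({
            "mode": cfg.mode,
            "re": cfg.re,
            "delta_um": res.grid.delta * 1e6,
            "final_alpha_um": s["final_alpha_um"],
            "final_mass_mg_per_cm2": s["final_mass_mg_per_cm2"],
        })
    df = pd.DataFrame(rows)
    ref = df[(df["mode"] == "10-10") & (df["re"] == 187)]
    if len(ref):
        a0 = float(ref["final_alpha_um"].iloc[0])
        m0 = float(ref["final_mass_mg_per_cm2"].iloc[0])
        df["alpha_change_pct"] = 100.0 * (df["final_alpha_um"] / a0 - 1.0)
        df["mass_change_pct"] = 100.0 * (df["final_mass_mg_per_cm2"] / m0 - 1.0)
    else:
        log.warning("reference scenario (10-10, Re 187) missing; "
                    "summary restricted to absolute values")
    return df
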