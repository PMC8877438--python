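"""Galvanostatic current waveforms for pulsed and continuous operation.

A pulsed-electric-field (PEF) mode "tau_on - tau_off" applies the pulse
current density for tau_on seconds, then zero current for tau_off seconds,
repeating until the charge of a reference continuous-current run has passed.
All modes here share i_pulse = 50 A/m^2 (5 mA/cm^2) and an equivalent
charge-passing time of 1800 s, so the total process durations are 60, 90,
129 and 180 min for pauses of 10, 20, 33 and 50 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

__all__ = ["PEFMode", "mode_from_name", "waveform", "total_duration",
           "sample_times", "switching_times", "MODE_NAMES"]


@dataclass(frozen=True)
class PEFMode:
    """A galvanostatic square waveform.

    tau_off = 0 represents continuous current (CC).  t_H is the H+ transport
    number in the cation-exchange layer of the bipolar membrane; 1 means the
    whole current generates protons.
    """

    name: str
    tau_on: float                     # s
    tau_off: float                    # s
    i_pulse: float = 50.0             # A/m^2
    t_H: float = 1.0                  # dimensionless
    equivalent_on_time: float = 1800.0  # s of charge-passing time

    def __post_init__(self) -> None:
        if self.tau_on <= 0:
            raise ConfigurationError("tau_on must be positive")
        if self.tau_off < 0:
            raise ConfigurationError("tau_off must be non-negative")
        if not (0.0 < self.t_H <= 1.0):
            raise ConfigurationError("t_H must lie in (0, 1]")
        if self.i_pulse < 0:
            raise ConfigurationError("i_pulse must be non-negative")
        if self.equivalent_on_time <= 0:
            raise ConfigurationError("equivalent_on_time must be positive")

    @property
    def period(self) -> float:
        return self.tau_on + self.tau_off

    @property
    def is_continuous(self) -> bool:
        return self.tau_off == 0.0


_STANDARD = {
    "10-10": (10.0, 10.0),
    "10-20": (10.0, 20.0),
    "10-33": (10.0, 33.0),
    "10-50": (10.0, 50.0),
    "cc": (10.0, 0.0),  # tau_on is irrelevant for CC; duration = on-time
}

MODE_NAMES = tuple(_STANDARD)


def mode_from_name(name: str, **overrides) -> PEFMode:
    """Build one of the standard modes ("10-10", "10-20", "10-33", "10-50", "cc").

    Keyword overrides (i_pulse, equivalent_on_time, ...) are forwarded to the
    :class:`PEFMode` constructor.
    """
    key = name.lower().replace("–", "-")
    if key not in _STANDARD:
        raise ConfigurationError(
            f"unknown PEF mode {name!r}; expected one of {', '.join(_STANDARD)}"
        )
    tau_on, tau_off = _STANDARD[key]
    mode = PEFMode(name=key, tau_on=tau_on, tau_off=tau_off)
    return replace(mode, **overrides) if overrides else mode


def n_periods(mode: PEFMode) -> int:
    """Number of full periods needed to pass the equivalent charge."""
    return math.ceil(mode.equivalent_on_time / mode.tau_on - 1e-12)


def total_duration(mode: PEFMode) -> float:
    """Total process duration (s) under charge equivalence.

    The on-time is stretched by the duty cycle and rounded up to a whole
    number of periods; CC simply runs for the equivalent on-time.
    """
    if mode.is_continuous:
        return mode.equivalent_on_time
    return n_periods(mode) * mode.period


def waveform(mode: PEFMode, t: float | np.ndarray) -> float | np.ndarray:
    """Current density i(t) in A/m^2: i_pulse during pulses, 0 during pauses.

    Zero after the total duration.  The left limit is used at switching
    instants (i(tau_on) is already 0 for a pulsed mode).
    """
    t = np.asarray(t, dtype=float)
    T = total_duration(mode)
    if mode.is_continuous:
        out = np.where((t >= 0) & (t < T), mode.i_pulse, 0.0)
    else:
        phase = np.mod(t, mode.period)
        out = np.where((t >= 0) & (t < T) & (phase < mode.tau_on), mode.i_pulse, 0.0)
    return float(out) if out.ndim == 0 else out


def switching_times(mode: PEFMode) -> np.ndarray:
    """All instants where i(t) jumps, including 0 and the total duration."""
    if mode.is_continuous:
        return np.array([0.0, total_duration(mode)])
    k = n_periods(mode)
    starts = np.arange(k) * mode.period
    times = np.concatenate([starts, starts + mode.tau_on, [k * mode.period]])
    return np.unique(times)


def sample_times(mode: PEFMode, epsilon: float = 0.4) -> tuple[float, float]:
    """Canonical profile-sampling times in the final full period.

    Returns ``(end_of_pulse, end_of_pause)``, each ``epsilon`` seconds before
    the corresponding switching instant so that profiles are sampled on the
    smooth side of the discontinuity.  For CC both times refer to the end of
    the single current-on interval.
    """
    if not (0.0 <= epsilon < mode.tau_on):
        raise ConfigurationError("epsilon must satisfy 0 <= epsilon < tau_on")
    T = total_duration(mode)
    if mode.is_continuous:
        return (T - epsilon, T - epsilon)
    period_start = T - mode.period
    return (period_start + mode.tau_on - epsilon, T - epsilon)
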