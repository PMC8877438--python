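"""Galvanostatic pulse schedules and charge-equivalent process durations.

All pulsed modes deliver the same charge as 30 minutes of continuous
current at 50 A/m^2, so longer pauses stretch the total process time.
"""

from foulsim import mode_from_name, sample_times, total_duration, waveform

for name in ("10-10", "10-20", "10-33", "10-50", "cc"):
    m = mode_from_name(name)
    T = total_duration(m)
    t_pulse, t_pause = sample_times(m)
    print(f"mode {name:>5}: total {T:7.0f} s ({T / 60:5.1f} min), "
          f"i(5 s) = {waveform(m, 5.0):.0f} A/m^2, "
          f"i(15 s) = {waveform(m, 15.0):.0f} A/m^2, "
          f"profile samples at {t_pulse:.1f} / {t_pause:.1f} s")

print()
print("The sample times sit 0.4 s before the last switching instants, on the")
print("smooth side of the current discontinuity.")
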