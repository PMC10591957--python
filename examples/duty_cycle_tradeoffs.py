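"""Duty-cycle timing trade-offs: windows vs sampling frequency.

Builds DIA duty cycles with 2-16 MS2 isolation windows at Q-Exactive
settings (70k resolving power, 300 ms maximum injection time) and
prints, for each: the cycle duration, how many data points it collects
across a typical 2.5 s-sigma elution peak, and the median fraction of
the apex intensity the MS1 sampling grid captures. More windows means
less co-isolation but slower sampling: the cycle with 16 windows
samples precursors only every 5.1 s and routinely misses elution
apexes.
"""

from diaqc import dutycycle as dc
from diaqc import windows

peak = dc.ElutionPeak(sigma_s=2.5)

print(f"{'MS2 windows':>12} {'cycle (s)':>10} {'points/peak':>12} "
      f"{'median apex fraction':>21}")
for n in (2, 4, 6, 8, 10, 12, 16):
    scheme = windows.equal_mz_windows((380.0, 1400.0), n)
    spec = dc.DutyCycleSpec(n_ms1=1, scheme=scheme, resolving_power=70000,
                            max_injection_ms=300.0)
    cycle = dc.cycle_time_s(spec)
    ppp = dc.points_per_peak(peak, cycle)
    apex = dc.apex_sampling_ratio(peak, dc.ms1_sampling_interval_s(spec),
                                  phase="median")
    print(f"{n:>12d} {cycle:>10.1f} {ppp:>12.2f} {apex:>21.3f}")

print()
two = dc.DutyCycleSpec(n_ms1=2, scheme=windows.equal_mz_windows((380, 1400), 8),
                       max_injection_ms=251.0)
one = dc.DutyCycleSpec(n_ms1=1, scheme=windows.equal_mz_windows((380, 1400), 8),
                       max_injection_ms=251.0)
print("8 MS2 windows, 251 ms max injection:")
print(f"  1 survey scan : MS1 interval {dc.ms1_sampling_interval_s(one):.2f} s")
print(f"  2 survey scans: MS1 interval {dc.ms1_sampling_interval_s(two):.2f} s "
      f"(cycle only {dc.cycle_time_s(two) / dc.cycle_time_s(one):.2f}x longer)")
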