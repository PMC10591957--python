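"""Acquisition duty-cycle timing model for Orbitrap-style DIA methods.

A duty cycle is the repeating schedule of MS1 survey scans and MS2
fragmentation scans. Its duration sets how often each precursor is
sampled across its chromatographic elution peak, which in turn bounds
quantitative accuracy: a slow cycle can miss the elution apex entirely.

The per-scan time model is ``max(transient, max injection time) +
overhead``. On Orbitraps ion accumulation for the next scan proceeds in
parallel with the previous transient, so whichever of the two is longer
dominates; overhead (ion routing, electronics) defaults to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .windows import WindowScheme

__all__ = [
    "ORBITRAP_TRANSIENT_MS",
    "DutyCycleSpec",
    "ElutionPeak",
    "transient_ms",
    "scan_time_ms",
    "cycle_time_s",
    "scan_schedule",
    "ms1_sampling_interval_s",
    "apex_sampling_ratio",
    "points_per_peak",
]

#: Orbitrap transient duration (ms) per resolving-power setting.
#: Follows the standard doubling law: doubling the resolving power
#: doubles the transient. Overridable per call for other instruments.
ORBITRAP_TRANSIENT_MS: dict[int, float] = {
    17500: 64.0,
    35000: 128.0,
    70000: 256.0,
    140000: 512.0,
}


def transient_ms(resolving_power: int, table: dict[int, float] | None = None) -> float:
    """Transient duration in ms for an Orbitrap resolving-power setting.

    Parameters
    ----------
    resolving_power:
        Nominal resolving power (at m/z 200), e.g. 70000.
    table:
        Optional replacement transient table for non-default instruments.
    """
    table = ORBITRAP_TRANSIENT_MS if table is None else table
    try:
        return table[int(resolving_power)]
    except KeyError:
        raise ConfigError(
            f"resolving power {resolving_power} not in transient table "
            f"{sorted(table)}"
        ) from None


@dataclass(frozen=True)
class ElutionPeak:
    """Gaussian chromatographic elution peak.

    sigma_s is the Gaussian standard deviation in seconds; the base
    width used for points-per-peak accounting is 4*sigma.
    """

    sigma_s: float
    apex_rt_s: float = 0.0
    apex_intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ConfigError("sigma_s must be positive")
        if self.apex_intensity <= 0:
            raise ConfigError("apex_intensity must be positive")


@dataclass(frozen=True)
class DutyCycleSpec:
    """One acquisition duty cycle: survey scans, MS2 scheme, timing settings.

    ``ms1_positions`` are 0-based slot indices of the survey scans within
    the cycle's scan sequence of length ``n_ms1 + n_ms2``; MS2 scans fill
    the remaining slots in window order.
    """

    n_ms1: int
    scheme: WindowScheme
    resolving_power: int = 70000
    max_injection_ms: float = 300.0
    overhead_ms: float = 0.0
    ms1_positions: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_ms1 < 1:
            raise ConfigError("n_ms1 must be >= 1")
        if self.max_injection_ms <= 0:
            raise ConfigError("max_injection_ms must be positive")
        if self.overhead_ms < 0:
            raise ConfigError("overhead_ms must be non-negative")
        if self.ms1_positions is None:
            object.__setattr__(
                self, "ms1_positions", _even_positions(self.n_ms1, self.n_scans)
            )
        else:
            object.__setattr__(self, "ms1_positions", tuple(self.ms1_positions))
        pos = self.ms1_positions
        if len(pos) != self.n_ms1:
            raise ConfigError("len(ms1_positions) must equal n_ms1")
        if list(pos) != sorted(set(pos)):
            raise ConfigError("ms1_positions must be strictly increasing")
        if pos and (pos[0] < 0 or pos[-1] >= self.n_scans):
            raise ConfigError("ms1_positions out of range")

    @property
    def n_ms2(self) -> int:
        return len(self.scheme.windows)

    @property
    def n_scans(self) -> int:
        return self.n_ms1 + self.n_ms2


def _even_positions(n_ms1: int, n_scans: int) -> tuple[int, ...]:
    """Survey-scan slots spread evenly through the cycle, first at slot 0."""
    return tuple(int(round(k * n_scans / n_ms1)) for k in range(n_ms1))


def scan_time_ms(spec: DutyCycleSpec) -> float:
    """Duration of one scan: max(transient, max injection) + overhead.

    Identical for MS1 and MS2 scans acquired at the same settings.
    """
    return (
        max(transient_ms(spec.resolving_power), spec.max_injection_ms)
        + spec.overhead_ms
    )


def cycle_time_s(spec: DutyCycleSpec) -> float:
    """Total duty-cycle duration in seconds."""
    return spec.n_scans * scan_time_ms(spec) / 1000.0


def scan_schedule(spec: DutyCycleSpec) -> list[tuple[int, int, int | None]]:
    """Scan-by-scan schedule of one cycle.

    Returns a list of ``(slot, ms_level, window_index)`` with
    ``window_index`` None for MS1 slots and the 0-based isolation-window
    index for MS2 slots (windows assigned low-to-high m/z in slot order).
    """
    ms1 = set(spec.ms1_positions)
    out: list[tuple[int, int, int | None]] = []
    w = 0
    for slot in range(spec.n_scans):
        if slot in ms1:
            out.append((slot, 1, None))
        else:
            out.append((slot, 2, w))
            w += 1
    return out


def ms1_sampling_interval_s(spec: DutyCycleSpec) -> float:
    """Maximum time between consecutive MS1 scans, wrapping across cycles.

    For a single survey scan this equals the cycle time; for several
    survey scans it is the largest slot gap times the per-scan time, so
    unevenly placed surveys are penalised by their worst gap.
    """
    pos = spec.ms1_positions
    n = spec.n_scans
    gaps = [b - a for a, b in zip(pos, pos[1:])]
    gaps.append(pos[0] + n - pos[-1])  # wrap into the next cycle
    return max(gaps) * scan_time_ms(spec) / 1000.0


def apex_sampling_ratio(
    peak: ElutionPeak, interval_s: float, phase: float | str = "median"
) -> float:
    """Fraction of the apex intensity captured by the best-placed sample.

    A Gaussian peak sampled on a grid of spacing ``interval_s`` attains
    at best ``exp(-d^2 / (2 sigma^2))`` of its apex, where d is the
    distance from the apex to the nearest grid point. ``phase`` may be a
    numeric grid offset in seconds, or "median" for the median ratio
    over a uniformly random phase (d = interval/4, since d is uniform on
    [0, interval/2]).
    """
    if interval_s <= 0:
        raise ConfigError("interval_s must be positive")
    half = interval_s / 2.0
    if phase == "median":
        d = interval_s / 4.0
    else:
        # distance from apex to nearest sample of the grid {phase + k*interval}
        off = (peak.apex_rt_s - float(phase)) % interval_s
        d = min(off, interval_s - off)
        d = min(d, half)
    return math.exp(-(d * d) / (2.0 * peak.sigma_s**2))


def apex_sampling_ratio_mc(
    peak: ElutionPeak,
    interval_s: float,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo median apex-sampling ratio over a uniform grid phase.

    Cross-check for the closed form exp(-interval^2 / (32 sigma^2)).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    phase = rng.uniform(0.0, interval_s, size=n_draws)
    d = np.minimum(phase, interval_s - phase)
    ratios = np.exp(-(d**2) / (2.0 * peak.sigma_s**2))
    return float(np.median(ratios))


def points_per_peak(peak: ElutionPeak, cycle_s: float) -> float:
    """Number of sampling points across the peak base (4 sigma) per cycle."""
    if cycle_s <= 0:
        raise ConfigError("cycle_s must be positive")
    return 4.0 * peak.sigma_s / cycle_s
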