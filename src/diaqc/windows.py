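"""MS2 isolation-window placement strategies.

DIA methods tile the precursor m/z range with contiguous isolation
windows. Because peptide precursors are not uniform in m/z, equal-width
windows concentrate most ions in the low-m/z windows: those fill the
trap in milliseconds while high-m/z windows idle at the maximum
accumulation time. The data-driven strategies here re-tile the range so
each window receives an equal share of ion current (from an observed
MS1 intensity-vs-m/z histogram) or an equal number of identified
precursors (from a search report).

Window convention is half-open ``[lower, upper)``: a precursor exactly
on a boundary belongs to the upper window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError

__all__ = [
    "WindowScheme",
    "MzHistogram",
    "equal_mz_windows",
    "equal_tic_windows",
    "equal_precursor_windows",
    "scheme_upper_edge",
    "validate_scheme",
]

_EDGE_TOL = 1e-9  # Th; contiguity / total-width tolerance


@dataclass(frozen=True)
class WindowScheme:
    """An ordered, contiguous tiling of a precursor m/z range.

    ``windows`` is a tuple of ``(lower_mz, upper_mz)`` pairs in Th;
    ``mz_range`` is the full precursor range the tiling must cover.
    """

    windows: tuple[tuple[float, float], ...]
    mz_range: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "windows", tuple((float(a), float(b)) for a, b in self.windows)
        )
        object.__setattr__(
            self, "mz_range", (float(self.mz_range[0]), float(self.mz_range[1]))
        )

    @property
    def widths(self) -> tuple[float, ...]:
        return tuple(b - a for a, b in self.windows)

    @property
    def edges(self) -> tuple[float, ...]:
        """All n+1 boundaries, low to high."""
        return tuple([w[0] for w in self.windows] + [self.windows[-1][1]])

    def assign(self, mz: np.ndarray) -> np.ndarray:
        """0-based window index per m/z value; -1 outside the range.

        Half-open windows: a value on an interior boundary goes to the
        upper window; the top edge of the last window is inclusive so
        the range upper bound itself is still assignable.
        """
        mz = np.asarray(mz, dtype=float)
        edges = np.asarray(self.edges)
        idx = np.searchsorted(edges, mz, side="right") - 1
        idx[mz == edges[-1]] = len(self.windows) - 1
        idx[(mz < edges[0]) | (mz > edges[-1])] = -1
        return idx

    def rounded(self, step: float = 0.5) -> "WindowScheme":
        """Boundaries rounded to a step (Th) for instrument export.

        Interior boundaries are snapped to the nearest multiple of
        ``step``; the outer edges keep the exact range.
        """
        edges = list(self.edges)
        snapped = [edges[0]] + [
            round(e / step) * step for e in edges[1:-1]
        ] + [edges[-1]]
        scheme = WindowScheme(
            tuple(zip(snapped[:-1], snapped[1:])), self.mz_range
        )
        bad = validate_scheme(scheme)
        if bad:
            raise DegenerateInputError(
                "rounding produced an invalid scheme: " + "; ".join(bad)
            )
        return scheme

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_index": np.arange(len(self.windows)),
                "lower_mz": [w[0] for w in self.windows],
                "upper_mz": [w[1] for w in self.windows],
                "width": list(self.widths),
            }
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    def method_table_text(self) -> str:
        """One-line description in acquisition-method style."""
        widths = ", ".join(f"{w:g}Th" for w in self.widths)
        return f"starting at {self.mz_range[0]:g} mz: {widths} width"


@dataclass(frozen=True)
class MzHistogram:
    """Empirical ion current vs m/z: summed MS1 intensity per m/z bin."""

    bin_edges: np.ndarray
    bin_mass: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        mass = np.asarray(self.bin_mass, dtype=float)
        if len(mass) != len(edges) - 1:
            raise ConfigError("len(bin_mass) must be len(bin_edges) - 1")
        if np.any(np.diff(edges) <= 0):
            raise ConfigError("bin_edges must be strictly increasing")
        if np.any(mass < 0):
            raise ConfigError("bin_mass must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_mass", mass)

    @classmethod
    def from_scans(cls, scans, bin_width_th: float = 5.0) -> "MzHistogram":
        """Histogram of MS1 centroid intensity from a ScanTable with peaks."""
        lo, hi = scans.metadata.precursor_range
        edges = np.arange(lo, hi + bin_width_th, bin_width_th)
        mass = np.zeros(len(edges) - 1)
        for rec in scans.ms1_scans():
            if rec.mz is None:
                raise DegenerateInputError("peaks not loaded; cannot histogram m/z")
            if len(rec.mz):
                mass += np.histogram(rec.mz, bins=edges, weights=rec.intensity)[0]
        return cls(edges, mass)


def equal_mz_windows(mz_range: tuple[float, float], n: int) -> WindowScheme:
    """n windows of identical width covering the range."""
    lo, hi = float(mz_range[0]), float(mz_range[1])
    if n < 1:
        raise ConfigError("n must be >= 1")
    if hi <= lo:
        raise ConfigError("mz_range upper must exceed lower")
    edges = np.linspace(lo, hi, n + 1)
    return WindowScheme(tuple(zip(edges[:-1], edges[1:])), (lo, hi))


def equal_tic_windows(
    hist: MzHistogram, mz_range: tuple[float, float], n: int
) -> WindowScheme:
    """Windows holding equal total ion current, from an m/z histogram.

    Boundaries sit at the k/n quantiles of the cumulative bin mass,
    linearly interpolated inside bins so the result converges as the
    histogram bin width shrinks. Runs of zero-mass bins that would
    collapse several boundaries onto one point are spread evenly across
    the zero-mass span.
    """
    lo, hi = float(mz_range[0]), float(mz_range[1])
    if n < 1:
        raise ConfigError("n must be >= 1")
    if hist.bin_edges[0] > lo + _EDGE_TOL or hist.bin_edges[-1] < hi - _EDGE_TOL:
        raise ConfigError("histogram does not cover the requested m/z range")
    edges, mass = _clip_hist(hist, lo, hi)
    total = mass.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero m/z histogram")
    cum = np.concatenate([[0.0], np.cumsum(mass)])
    cuts = [lo]
    for k in range(1, n):
        target = k * total / n
        j = int(np.searchsorted(cum, target, side="right") - 1)
        j = min(j, len(mass) - 1)
        if mass[j] > 0:
            frac = (target - cum[j]) / mass[j]
        else:  # target falls exactly on the cumulative value of a zero bin
            frac = 0.0
        cuts.append(edges[j] + frac * (edges[j + 1] - edges[j]))
    cuts.append(hi)
    cuts = _spread_duplicates(cuts)
    return WindowScheme(tuple(zip(cuts[:-1], cuts[1:])), (lo, hi))


def _clip_hist(hist: MzHistogram, lo: float, hi: float):
    """Restrict a histogram to [lo, hi], pro-rating partial edge bins."""
    edges = hist.bin_edges
    mass = hist.bin_mass.copy()
    new_edges = np.clip(edges, lo, hi)
    widths = np.diff(edges)
    kept = np.diff(new_edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(widths > 0, kept / widths, 0.0)
    mass = mass * frac
    keep = kept > 0
    # rebuild edge list for kept bins (they are contiguous by construction)
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        return np.array([lo, hi]), np.array([0.0])
    e = np.concatenate([[new_edges[idx[0]]], new_edges[idx + 1]])
    return e, mass[keep]


def _spread_duplicates(cuts: list[float]) -> list[float]:
    """Make boundaries strictly increasing by spreading tied runs evenly."""
    out = list(cuts)
    i = 0
    while i < len(out) - 1:
        j = i
        while j + 1 < len(out) and out[j + 1] <= out[i]:
            j += 1
        if j > i:
            nxt = out[j + 1] if j + 1 < len(out) else out[i]
            for m in range(i + 1, j + 1):
                out[m] = out[i] + (nxt - out[i]) * (m - i) / (j + 1 - i)
        i = j + 1 if j > i else i + 1
    return out


def equal_precursor_windows(
    precursor_mzs: Sequence[float], mz_range: tuple[float, float], n: int
) -> WindowScheme:
    """Windows holding equal numbers of observed precursors.

    Boundaries are placed at the midpoint between the order statistics
    flanking each empirical k/n quantile, so per-window counts differ by
    at most one. If duplicated m/z values straddle a cut, the cut is
    shifted to the nearest flanking position that keeps counts balanced.
    """
    lo, hi = float(mz_range[0]), float(mz_range[1])
    if n < 1:
        raise ConfigError("n must be >= 1")
    mzs = np.sort(np.asarray(precursor_mzs, dtype=float))
    mzs = mzs[(mzs >= lo) & (mzs <= hi)]
    m = len(mzs)
    if m < n:
        raise ConfigError(f"need at least {n} precursors in range, got {m}")
    cuts = [lo]
    for k in range(1, n):
        c = (k * m) // n
        c = _shift_off_ties(mzs, c)
        cuts.append((mzs[c - 1] + mzs[c]) / 2.0)
    cuts.append(hi)
    cuts = _spread_duplicates(cuts)
    return WindowScheme(tuple(zip(cuts[:-1], cuts[1:])), (lo, hi))


def _shift_off_ties(sorted_mzs: np.ndarray, c: int) -> int:
    """Move a cut index off a run of duplicate values, preferring the
    nearest end of the run."""
    m = len(sorted_mzs)
    c = max(1, min(c, m - 1))
    if sorted_mzs[c - 1] != sorted_mzs[c]:
        return c
    v = sorted_mzs[c]
    left = np.searchsorted(sorted_mzs, v, side="left")
    right = np.searchsorted(sorted_mzs, v, side="right")
    lo_ok = left >= 1
    hi_ok = right <= m - 1
    if lo_ok and (not hi_ok or c - left <= right - c):
        return int(left)
    if hi_ok:
        return int(right)
    return c  # entire array is one value; caller's spread handles it


def scheme_upper_edge(widths: Sequence[float], start: float) -> float:
    """Upper m/z edge of a stack of window widths beginning at ``start``."""
    widths = np.asarray(widths, dtype=float)
    if np.any(widths <= 0):
        raise ConfigError("widths must be positive")
    return float(start + widths.sum())


def validate_scheme(scheme: WindowScheme) -> list[str]:
    """All invariant violations of a scheme; empty list means valid."""
    out: list[str] = []
    win = scheme.windows
    lo, hi = scheme.mz_range
    if not win:
        return ["scheme has no windows"]
    for i, (a, b) in enumerate(win):
        if b - a <= 0:
            out.append(f"window {i} has non-positive width ({a}, {b})")
    for i in range(len(win) - 1):
        if abs(win[i][1] - win[i + 1][0]) > _EDGE_TOL:
            out.append(
                f"windows {i} and {i + 1} not contiguous: "
                f"{win[i][1]} != {win[i + 1][0]}"
            )
    if abs(win[0][0] - lo) > _EDGE_TOL:
        out.append(f"first lower edge {win[0][0]} != range lower {lo}")
    if abs(win[-1][1] - hi) > _EDGE_TOL:
        out.append(f"last upper edge {win[-1][1]} != range upper {hi}")
    if abs(sum(scheme.widths) - (hi - lo)) > _EDGE_TOL:
        out.append("sum of widths does not equal range width")
    return out
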