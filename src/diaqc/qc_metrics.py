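"""Report metrics for DIA / plexDIA acquisition quality control.

Everything here reduces a ScanTable (per-scan acquisition metadata)
and/or a PrecursorTable (search-report rows) to the summary statistics
a method-optimisation report is built from: identification counts and
FDR curves, data completeness (Jaccard overlap of identification sets),
within-protein quantification variability, intensity and ratio
distributions per plexDIA channel, MS2 accumulation time per isolation
window across the gradient, TIC ion maps, and precursor signal-to-noise.

Cross-channel comparisons identify a precursor by its stripped sequence
and charge, so the channel-specific label tag does not make channels
artificially disjoint; cross-run comparisons keep the modified sequence.
All binning is half-open ``[lower, upper)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError
from .report_io import PrecursorTable
from .scan_io import ScanTable

log = logging.getLogger(__name__)

__all__ = [
    "BinnedSeries",
    "CompletenessMatrix",
    "jaccard_completeness",
    "completeness_matrix",
    "quant_variability",
    "intensity_distribution",
    "ratio_distribution",
    "RatioSummary",
    "id_counts",
    "protein_overlap_counts",
    "ms1_quant_fraction",
    "ids_vs_fdr",
    "ids_per_rt_bin",
    "accumulation_by_window",
    "injection_time_by_window",
    "tic_map",
    "mean_mz_trace",
    "precursor_sn",
]


@dataclass(frozen=True)
class BinnedSeries:
    """One binned metric track: values per half-open bin, plus its
    aggregation statistic and an optional group label (window, channel,
    run)."""

    bin_edges: np.ndarray
    values: np.ndarray
    statistic: str = "mean"
    group: str | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if len(vals) != len(edges) - 1:
            raise ConfigError("len(values) must be len(bin_edges) - 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "values", vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lower": self.bin_edges[:-1],
                "bin_upper": self.bin_edges[1:],
                "value": self.values,
                "statistic": self.statistic,
                "group": self.group if self.group is not None else "",
            }
        )


@dataclass(frozen=True)
class CompletenessMatrix:
    """Pairwise Jaccard overlap of identification sets."""

    labels: tuple[str, ...]
    J: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.J, index=list(self.labels), columns=list(self.labels))


def jaccard_completeness(ids_a: Iterable, ids_b: Iterable) -> float:
    """Jaccard index |A n B| / |A u B| of two identification sets.

    Two empty sets are treated as complete (1.0) and logged, since no
    identification was missed by either side.
    """
    a, b = set(ids_a), set(ids_b)
    union = a | b
    if not union:
        log.info("Jaccard of two empty identification sets; returning 1.0")
        return 1.0
    return len(a & b) / len(union)


def _id_sets(
    table: PrecursorTable, by: str, id_key: str
) -> dict[str, set]:
    df = table.df
    if by not in ("channel", "run"):
        raise ConfigError(f"by must be 'channel' or 'run', got {by!r}")
    group_col = "channel" if by == "channel" else "run_id"
    if id_key == "precursor":
        # stripped sequence + charge: comparable across channels
        ids = list(zip(df["stripped_sequence"], df["charge"]))
    elif id_key == "protein":
        ids = list(df["protein_group"])
    else:
        raise ConfigError(f"id_key must be 'precursor' or 'protein', got {id_key!r}")
    out: dict[str, set] = {}
    for group, members in zip(df[group_col], ids):
        out.setdefault(group, set()).add(members)
    return out


def completeness_matrix(
    table: PrecursorTable, by: str = "channel", id_key: str = "precursor"
) -> CompletenessMatrix:
    """Pairwise Jaccard completeness between channels or runs."""
    sets = _id_sets(table, by, id_key)
    labels = sorted(sets)
    if len(labels) < 2:
        raise ConfigError("completeness needs at least two groups")
    n = len(labels)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = jaccard_completeness(sets[labels[i]], sets[labels[j]])
    return CompletenessMatrix(tuple(labels), J)


def quant_variability(
    table: PrecursorTable,
    min_peptides: int = 3,
    cell_key: Sequence[str] = ("run_id", "channel"),
    quantity: str = "ms1_intensity",
) -> pd.Series:
    """Median within-protein coefficient of variation per cell.

    A "cell" is one sample, keyed by run x channel by default. Charge
    states of a peptide (stripped sequence) are collapsed by summed
    intensity; each cell is first normalised by its median peptide
    intensity (so a global per-cell scale factor cancels exactly), then
    each peptide's value is divided by its mean across cells (relative
    level); the CV (sample SD / mean, ddof=1) is computed per protein
    with at least ``min_peptides`` quantified peptides; the cell's score
    is the median CV over its proteins, NaN when no protein qualifies.
    """
    df = table.df
    df = df[df[quantity].notna() & (df[quantity] > 0)]
    cell_key = list(cell_key)
    pep = (
        df.groupby(cell_key + ["protein_group", "stripped_sequence"], sort=True)[
            quantity
        ]
        .sum()
        .reset_index(name="value")
    )
    cell_median = pep.groupby(cell_key)["value"].transform("median")
    pep["value"] = pep["value"] / cell_median
    mean_across_cells = pep.groupby(["protein_group", "stripped_sequence"])[
        "value"
    ].transform("mean")
    pep["rel"] = pep["value"] / mean_across_cells

    def _protein_cv(g: pd.DataFrame) -> float:
        if g["stripped_sequence"].nunique() < min_peptides:
            return np.nan
        vals = g["rel"].to_numpy(float)
        m = vals.mean()
        return float(vals.std(ddof=1) / m) if m > 0 else np.nan

    cv = (
        pep.groupby(cell_key + ["protein_group"])
        .apply(_protein_cv, include_groups=False)
        .rename("cv")
        .reset_index()
    )
    out = cv.groupby(cell_key)["cv"].median()
    out.name = "median_protein_cv"
    return out


def intensity_distribution(
    table: PrecursorTable,
    by_channel: bool = True,
    quantity: str = "ms1_intensity",
    bin_width: float = 0.1,
) -> list[BinnedSeries]:
    """log10 precursor-intensity histogram per channel (or run).

    Bin edges are shared across groups (aligned to multiples of the bin
    width) so the per-channel histograms are directly comparable.
    """
    df = table.df
    df = df[df[quantity].notna() & (df[quantity] > 0)]
    if df.empty:
        return []
    logv = np.log10(df[quantity].to_numpy(float))
    lo = math.floor(logv.min() / bin_width) * bin_width
    hi = math.ceil(logv.max() / bin_width) * bin_width
    # one spare bin keeps the maximum off the (inclusive) final edge, so
    # every bin is effectively half-open
    n_bins = max(1, int(round((hi - lo) / bin_width))) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    group_col = "channel" if by_channel else "run_id"
    out = []
    for group, sub in df.groupby(group_col, sort=True):
        counts, _ = np.histogram(
            np.log10(sub[quantity].to_numpy(float)), bins=edges
        )
        out.append(
            BinnedSeries(edges, counts.astype(float), statistic="count", group=str(group))
        )
    return out


@dataclass(frozen=True)
class RatioSummary:
    """log2 intensity ratios of one group against the reference group."""

    group: str
    log2_ratios: np.ndarray
    median: float


def ratio_distribution(
    table: PrecursorTable,
    reference: str,
    by: str = "run",
    quantity: str = "ms1_intensity",
) -> dict[str, RatioSummary]:
    """Per-group log2 intensity ratios relative to a reference group.

    Only precursors identified and quantified in every compared group
    (the intersected set) contribute, so missing-value structure does
    not bias the ratio distributions. ``by`` selects runs (the classic
    method-comparison view) or plexDIA channels within a run.
    """
    df = table.df
    df = df[df[quantity].notna() & (df[quantity] > 0)]
    group_col = "run_id" if by == "run" else "channel"
    key = (
        ["modified_sequence", "charge"]
        if by == "run"
        else ["stripped_sequence", "charge"]
    )
    groups = sorted(df[group_col].unique())
    if reference not in groups:
        raise ConfigError(f"reference group {reference!r} not present")
    if len(groups) < 2:
        raise ConfigError("ratio distribution needs at least two groups")
    wide = df.pivot_table(
        index=key, columns=group_col, values=quantity, aggfunc="sum"
    ).dropna()
    if wide.empty:
        raise DegenerateInputError("no precursor common to all groups")
    out: dict[str, RatioSummary] = {}
    ref = wide[reference].to_numpy(float)
    for g in groups:
        ratios = np.log2(wide[g].to_numpy(float) / ref)
        out[g] = RatioSummary(group=g, log2_ratios=ratios, median=float(np.median(ratios)))
    return out


def id_counts(
    table: PrecursorTable,
    by: str = "run",
    split_translated: bool = False,
    level: str = "precursor",
) -> pd.DataFrame:
    """Distinct identification counts per run or channel.

    With ``split_translated`` the direct and propagated (translated)
    identifications are reported separately; an identification counts as
    direct in a group if any of its records there is direct.
    """
    df = table.df.copy()
    group_col = "run_id" if by == "run" else "channel"
    if level == "precursor":
        df["_id"] = list(zip(df["modified_sequence"], df["charge"]))
    elif level == "protein":
        df["_id"] = df["protein_group"]
    else:
        raise ConfigError(f"level must be 'precursor' or 'protein', got {level!r}")
    rows = []
    for group, sub in df.groupby(group_col, sort=True):
        direct_ids = set(sub.loc[~sub["translated"], "_id"])
        all_ids = set(sub["_id"])
        translated_ids = all_ids - direct_ids
        if split_translated:
            rows.append(
                {
                    "group": group,
                    "direct": len(direct_ids),
                    "translated": len(translated_ids),
                    "total": len(all_ids),
                }
            )
        else:
            rows.append({"group": group, "total": len(all_ids)})
    return pd.DataFrame(rows)


def protein_overlap_counts(table: PrecursorTable, by: str = "channel") -> dict:
    """Per-group protein counts plus the intersection and union across
    groups (the shared-versus-total view of a multiplexed set)."""
    sets = _id_sets(table, by, "protein")
    if not sets:
        return {"per_group": {}, "intersection": 0, "union": 0}
    values = list(sets.values())
    inter = set.intersection(*values)
    union = set.union(*values)
    return {
        "per_group": {g: len(s) for g, s in sorted(sets.items())},
        "intersection": len(inter),
        "union": len(union),
    }


def ms1_quant_fraction(table: PrecursorTable, by: str = "run") -> pd.Series:
    """Fraction of identified precursors that carry an MS1 quantity."""
    df = table.df
    group_col = "run_id" if by == "run" else "channel"
    return (
        df.groupby(group_col, sort=True)["ms1_intensity"]
        .apply(lambda s: float(s.notna().mean()))
        .rename("ms1_quant_fraction")
    )


def ids_vs_fdr(
    table: PrecursorTable, thresholds: Sequence[float] | None = None
) -> pd.DataFrame:
    """Identification count as a function of the q-value threshold.

    Expects an unfiltered table (read with ``q_threshold=1.0``); the
    count at threshold t is the number of records with q-value <= t and
    is non-decreasing in t.
    """
    if thresholds is None:
        thresholds = np.concatenate([[0.0], np.geomspace(1e-4, 1.0, 41)])
    q = np.sort(table.df["q_value"].to_numpy(float))
    t = np.asarray(list(thresholds), dtype=float)
    counts = np.searchsorted(q, t, side="right")
    return pd.DataFrame({"threshold": t, "n_ids": counts})


def ids_per_rt_bin(
    table: PrecursorTable, rt_bin_s: float = 60.0, by: str | None = None
) -> list[BinnedSeries]:
    """Identified precursors per retention-time bin (gradient profile of
    identifications), optionally grouped by run or channel."""
    df = table.df
    if df.empty:
        return []
    edges = _rt_edges(df["rt_seconds"].to_numpy(float), rt_bin_s)
    if by is None:
        counts, _ = np.histogram(df["rt_seconds"], bins=edges)
        return [BinnedSeries(edges, counts.astype(float), statistic="count")]
    group_col = "run_id" if by == "run" else "channel"
    return [
        BinnedSeries(
            edges,
            np.histogram(sub["rt_seconds"], bins=edges)[0].astype(float),
            statistic="count",
            group=str(g),
        )
        for g, sub in df.groupby(group_col, sort=True)
    ]


def _rt_edges(rt: np.ndarray, rt_bin_s: float) -> np.ndarray:
    lo = math.floor(rt.min() / rt_bin_s) * rt_bin_s
    hi = math.ceil(rt.max() / rt_bin_s) * rt_bin_s
    if hi <= lo:
        hi = lo + rt_bin_s
    n = int(round((hi - lo) / rt_bin_s))
    return lo + rt_bin_s * np.arange(n + 1)


def accumulation_by_window(
    scans: ScanTable, rt_bin_s: float = 60.0
) -> list[BinnedSeries]:
    """Mean MS2 accumulation (injection) time per isolation window per RT bin.

    Scans are grouped by their (isolation center, width) pair; missing
    injection times are skipped. The per-window track across the
    gradient reveals windows that fill the trap instantly versus windows
    idling at the maximum accumulation time.
    """
    ms2 = scans.ms2_scans()
    if not ms2:
        return []
    rt = np.array([s.rt_seconds for s in ms2])
    edges = _rt_edges(rt, rt_bin_s)
    groups: dict[tuple[float, float], list] = {}
    for s in ms2:
        groups.setdefault(
            (s.isolation_center_mz, s.isolation_width_mz), []
        ).append(s)
    out = []
    for (center, width), members in sorted(groups.items()):
        sums = np.zeros(len(edges) - 1)
        counts = np.zeros(len(edges) - 1)
        for s in members:
            if math.isnan(s.injection_time_ms):
                continue
            b = min(int((s.rt_seconds - edges[0]) // rt_bin_s), len(sums) - 1)
            sums[b] += s.injection_time_ms
            counts[b] += 1
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out.append(
            BinnedSeries(edges, means, statistic="mean", group=f"{center:g}/{width:g}")
        )
    return out


def injection_time_by_window(scans: ScanTable) -> pd.DataFrame:
    """Overall mean MS2 injection time per isolation window (one row per
    window, sorted by center m/z)."""
    rows: dict[tuple[float, float], list[float]] = {}
    for s in scans.ms2_scans():
        if math.isnan(s.injection_time_ms):
            continue
        rows.setdefault((s.isolation_center_mz, s.isolation_width_mz), []).append(
            s.injection_time_ms
        )
    data = [
        {
            "isolation_center_mz": c,
            "isolation_width_mz": w,
            "mean_injection_ms": float(np.mean(v)),
            "n_scans": len(v),
        }
        for (c, w), v in sorted(rows.items())
    ]
    return pd.DataFrame(data)


def tic_map(
    scans: ScanTable, rt_bin_s: float = 60.0, mz_bin_th: float = 10.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Summed MS1 centroid intensity per (RT bin x m/z bin).

    Returns ``(rt_edges, mz_edges, matrix)`` with matrix shape
    ``(n_rt_bins, n_mz_bins)``. Requires peaks to be loaded.
    """
    ms1 = scans.ms1_scans()
    if not ms1:
        raise DegenerateInputError("no MS1 scans")
    if any(s.mz is None for s in ms1):
        raise DegenerateInputError("MS1 peaks not loaded")
    rt = np.array([s.rt_seconds for s in ms1])
    rt_edges = _rt_edges(rt, rt_bin_s)
    lo, hi = scans.metadata.precursor_range
    n_mz = int(math.ceil((hi - lo) / mz_bin_th))
    mz_edges = lo + mz_bin_th * np.arange(n_mz + 1)
    mat = np.zeros((len(rt_edges) - 1, n_mz))
    for s in ms1:
        if not len(s.mz):
            continue
        b = min(int((s.rt_seconds - rt_edges[0]) // rt_bin_s), mat.shape[0] - 1)
        hist, _ = np.histogram(s.mz, bins=mz_edges, weights=s.intensity)
        mat[b] += hist
    return rt_edges, mz_edges, mat


def mean_mz_trace(scans: ScanTable, rt_bin_s: float = 60.0) -> BinnedSeries:
    """Intensity-weighted mean m/z of MS1 centroids per RT bin (the red
    trace over the TIC ion map); NaN for empty bins."""
    ms1 = scans.ms1_scans()
    if not ms1 or any(s.mz is None for s in ms1):
        raise DegenerateInputError("MS1 peaks not loaded")
    rt = np.array([s.rt_seconds for s in ms1])
    edges = _rt_edges(rt, rt_bin_s)
    w_sum = np.zeros(len(edges) - 1)
    wmz_sum = np.zeros(len(edges) - 1)
    for s in ms1:
        if not len(s.mz):
            continue
        b = min(int((s.rt_seconds - edges[0]) // rt_bin_s), len(w_sum) - 1)
        w_sum[b] += s.intensity.sum()
        wmz_sum[b] += float((s.mz * s.intensity).sum())
    with np.errstate(invalid="ignore"):
        trace = np.where(w_sum > 0, wmz_sum / np.maximum(w_sum, 1e-300), np.nan)
    return BinnedSeries(edges, trace, statistic="mean")


def precursor_sn(
    table: PrecursorTable,
    scans: ScanTable,
    ppm_tol: float = 10.0,
) -> pd.Series:
    """Per-record precursor signal-to-noise from MS1 centroid noise values.

    For each record the MS1 scan nearest in RT is searched for a centroid
    within ``ppm_tol`` of the precursor m/z; S/N is intensity / noise.
    NaN where no centroid matches, the precursor m/z is unknown, or the
    scan carries no noise array.
    """
    ms1 = [s for s in scans.ms1_scans() if s.mz is not None]
    if not ms1:
        return pd.Series(np.nan, index=table.df.index, name="sn")
    rts = np.array([s.rt_seconds for s in ms1])
    out = np.full(len(table.df), np.nan)
    mzs = table.df["precursor_mz"].to_numpy(float)
    recs_rt = table.df["rt_seconds"].to_numpy(float)
    for i, (mz, rt) in enumerate(zip(mzs, recs_rt)):
        if math.isnan(mz):
            continue
        scan = ms1[int(np.argmin(np.abs(rts - rt)))]
        if scan.noise is None or not len(scan.mz):
            continue
        j = int(np.argmin(np.abs(scan.mz - mz)))
        if abs(scan.mz[j] - mz) / mz * 1e6 <= ppm_tol and scan.noise[j] > 0:
            out[i] = scan.intensity[j] / scan.noise[j]
    return pd.Series(out, index=table.df.index, name="sn")
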