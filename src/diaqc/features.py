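"""Simplified peptide-like feature detection on centroided MS1 scans.

A feature is an ion trace: a centroid recurring at (nearly) the same
m/z across consecutive MS1 scans, giving a chromatographic elution
profile; a coeluting trace one isotope spacing higher assigns the
charge. This is a deliberately simple greedy trace builder — it chains
centroids within a ppm tolerance of a trace's running median m/z and
tolerates single-scan gaps — not a reimplementation of a full
isotope-pattern-scoring feature finder. Its purpose is counting and
profiling peptide-like ion signals (elution lengths, gradient
distribution, fraction explained by identified precursors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .report_io import PrecursorTable
from .scan_io import ScanTable

__all__ = [
    "ISOTOPE_SPACING_DA",
    "FeatureRecord",
    "detect_features",
    "feature_summary",
    "features_to_tsv",
    "read_feature_tsv",
]

ISOTOPE_SPACING_DA = 1.00335  # average peptide isotope mass difference


@dataclass
class FeatureRecord:
    """One detected ion trace with its elution profile summary."""

    mz_mono: float
    charge: int  # 0 = unknown
    rt_start_s: float
    rt_apex_s: float
    rt_end_s: float
    apex_intensity: float
    n_isotopes: int = 1
    n_scans: int = 1

    @property
    def elution_length_s(self) -> float:
        """Elution length at the base: RT span of the trace."""
        return self.rt_end_s - self.rt_start_s


class _Trace:
    __slots__ = ("mzs", "rts", "intensities", "miss")

    def __init__(self, mz: float, rt: float, intensity: float) -> None:
        self.mzs = [mz]
        self.rts = [rt]
        self.intensities = [intensity]
        self.miss = 0

    @property
    def median_mz(self) -> float:
        return float(np.median(self.mzs))


def detect_features(
    scans: ScanTable,
    ppm_tol: float = 10.0,
    min_scans: int = 3,
    isotope_check: bool = True,
    gap_tolerance: int = 1,
) -> list[FeatureRecord]:
    """Greedy MS1 trace building.

    Centroids in consecutive MS1 scans within ``ppm_tol`` of a running
    median m/z are chained (closest match wins, one centroid per trace
    per scan); a trace survives up to ``gap_tolerance`` missed scans.
    Traces spanning at least ``min_scans`` scans become features. With
    ``isotope_check`` a coeluting trace at +1.00335/z (z in 1..4) within
    the same tolerance assigns the charge and extends the isotope count;
    otherwise the charge stays 0 (unknown).
    """
    ms1 = scans.ms1_scans()
    if any(s.mz is None for s in ms1):
        raise DegenerateInputError("MS1 peaks not loaded")
    open_traces: list[_Trace] = []
    closed: list[_Trace] = []
    for scan in ms1:
        mz = scan.mz
        inten = scan.intensity
        order = np.argsort([t.median_mz for t in open_traces])
        open_sorted = [open_traces[i] for i in order]
        medians = np.array([t.median_mz for t in open_sorted])
        used = np.zeros(len(mz), dtype=bool)
        matched = set()
        for ti, trace in enumerate(open_sorted):
            med = medians[ti]
            tol = med * ppm_tol * 1e-6
            j = np.searchsorted(mz, med)
            best = -1
            best_d = tol
            for k in (j - 1, j):
                if 0 <= k < len(mz) and not used[k]:
                    d = abs(mz[k] - med)
                    if d <= best_d:
                        best, best_d = k, d
            if best >= 0:
                used[best] = True
                trace.mzs.append(float(mz[best]))
                trace.rts.append(scan.rt_seconds)
                trace.intensities.append(float(inten[best]))
                trace.miss = 0
                matched.add(id(trace))
        still_open: list[_Trace] = []
        for trace in open_sorted:
            if id(trace) in matched:
                still_open.append(trace)
            else:
                trace.miss += 1
                if trace.miss > gap_tolerance:
                    closed.append(trace)
                else:
                    still_open.append(trace)
        for k in range(len(mz)):
            if not used[k]:
                still_open.append(_Trace(float(mz[k]), scan.rt_seconds, float(inten[k])))
        open_traces = still_open
    closed.extend(open_traces)

    kept = [t for t in closed if len(t.rts) >= min_scans]
    features = []
    for t in kept:
        apex = int(np.argmax(t.intensities))
        features.append(
            FeatureRecord(
                mz_mono=t.median_mz,
                charge=0,
                rt_start_s=t.rts[0],
                rt_apex_s=t.rts[apex],
                rt_end_s=t.rts[-1],
                apex_intensity=float(t.intensities[apex]),
                n_isotopes=1,
                n_scans=len(t.rts),
            )
        )
    features.sort(key=lambda f: (f.mz_mono, f.rt_start_s))
    if isotope_check:
        features = _assign_charges(features, ppm_tol)
    return features


def _overlap(a: FeatureRecord, b: FeatureRecord) -> float:
    lo = max(a.rt_start_s, b.rt_start_s)
    hi = min(a.rt_end_s, b.rt_end_s)
    return hi - lo


def _assign_charges(
    features: list[FeatureRecord], ppm_tol: float
) -> list[FeatureRecord]:
    """Pair each feature with coeluting +1/z isotope traces to fix charge.

    Traces absorbed into an envelope are removed from the feature list:
    an envelope of k coeluting traces yields one monoisotopic feature
    with n_isotopes = k, as a feature finder would report it.
    """
    mzs = np.array([f.mz_mono for f in features])
    is_isotope = [False] * len(features)
    for i, f in enumerate(features):
        if is_isotope[i]:
            continue
        for z in (1, 2, 3, 4):
            n_iso = 1
            anchor = f
            while True:
                target = anchor.mz_mono + ISOTOPE_SPACING_DA / z
                tol = target * ppm_tol * 1e-6
                j = np.searchsorted(mzs, target)
                hit = -1
                for k in (j - 1, j, j + 1):
                    if (
                        0 <= k < len(features)
                        and not is_isotope[k]
                        and k != i
                        and abs(mzs[k] - target) <= tol
                        and _overlap(anchor, features[k]) > 0
                    ):
                        hit = k
                        break
                if hit < 0:
                    break
                is_isotope[hit] = True
                n_iso += 1
                anchor = features[hit]
            if n_iso > 1:
                f.charge = z
                f.n_isotopes = n_iso
                break
    return [f for f, iso in zip(features, is_isotope) if not iso]


def feature_summary(
    features: list[FeatureRecord],
    table: PrecursorTable | None = None,
    ppm_tol: float = 10.0,
    rt_bin_s: float = 60.0,
    length_bin_s: float = 2.0,
) -> dict:
    """Count-level summaries of a feature list.

    Returns the total feature count, features per RT bin, the elution
    length histogram, and — when a PrecursorTable is given — the
    fraction of features matched to an identified precursor (precursor
    m/z within ``ppm_tol`` of the feature m/z and RT inside the
    feature's elution span).
    """
    out: dict = {"n_features": len(features)}
    if not features:
        out.update(
            {
                "per_rt_bin": pd.DataFrame(columns=["bin_lower", "bin_upper", "count"]),
                "elution_length_hist": pd.DataFrame(
                    columns=["bin_lower", "bin_upper", "count"]
                ),
                "matched_fraction": np.nan,
            }
        )
        return out
    apex = np.array([f.rt_apex_s for f in features])
    lo = math.floor(apex.min() / rt_bin_s) * rt_bin_s
    hi = max(math.ceil(apex.max() / rt_bin_s) * rt_bin_s, lo + rt_bin_s)
    edges = np.arange(lo, hi + rt_bin_s / 2, rt_bin_s)
    counts, _ = np.histogram(apex, bins=edges)
    out["per_rt_bin"] = pd.DataFrame(
        {"bin_lower": edges[:-1], "bin_upper": edges[1:], "count": counts}
    )
    lengths = np.array([f.elution_length_s for f in features])
    ledges = np.arange(0.0, lengths.max() + length_bin_s, length_bin_s)
    if len(ledges) < 2:
        ledges = np.array([0.0, length_bin_s])
    lcounts, _ = np.histogram(lengths, bins=ledges)
    out["elution_length_hist"] = pd.DataFrame(
        {"bin_lower": ledges[:-1], "bin_upper": ledges[1:], "count": lcounts}
    )
    if table is not None and len(table.df):
        base_mz = table.df["precursor_mz"].to_numpy(float)
        base_rt = table.df["rt_seconds"].to_numpy(float)
        charge = table.df["charge"].to_numpy(float)
        ok = ~np.isnan(base_mz)
        base_mz, base_rt, charge = base_mz[ok], base_rt[ok], charge[ok]
        # a precursor explains its isotope peaks too: match features to
        # the first few isotope positions, not just the monoisotopic m/z
        ks = np.arange(3)
        prec_mz = (base_mz[:, None] + ISOTOPE_SPACING_DA * ks / charge[:, None]).ravel()
        prec_rt = np.repeat(base_rt, len(ks))
        order = np.argsort(prec_mz)
        prec_mz, prec_rt = prec_mz[order], prec_rt[order]
        matched = 0
        for f in features:
            tol = f.mz_mono * ppm_tol * 1e-6
            a = np.searchsorted(prec_mz, f.mz_mono - tol)
            b = np.searchsorted(prec_mz, f.mz_mono + tol)
            if np.any(
                (prec_rt[a:b] >= f.rt_start_s) & (prec_rt[a:b] <= f.rt_end_s)
            ):
                matched += 1
        out["matched_fraction"] = matched / len(features)
    else:
        out["matched_fraction"] = np.nan
    return out


_TSV_COLUMNS = {
    "mz": "mz_mono",
    "charge": "charge",
    "rtStart": "rt_start_s",
    "rtApex": "rt_apex_s",
    "rtEnd": "rt_end_s",
    "intensityApex": "apex_intensity",
    "nIsotopes": "n_isotopes",
    "nScans": "n_scans",
}


def features_to_tsv(features: list[FeatureRecord], path: str | Path) -> Path:
    """Write features in Dinosaur-style columns (RTs in minutes)."""
    path = Path(path)
    rows = []
    for f in features:
        rows.append(
            {
                "mz": f.mz_mono,
                "charge": f.charge,
                "rtStart": f.rt_start_s / 60.0,
                "rtApex": f.rt_apex_s / 60.0,
                "rtEnd": f.rt_end_s / 60.0,
                "intensityApex": f.apex_intensity,
                "nIsotopes": f.n_isotopes,
                "nScans": f.n_scans,
            }
        )
    pd.DataFrame(rows, columns=list(_TSV_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    return path


def read_feature_tsv(path: str | Path) -> list[FeatureRecord]:
    """Read a Dinosaur-style feature TSV (RTs in minutes) in place of
    running :func:`detect_features`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(
            FeatureRecord(
                mz_mono=float(r.mz),
                charge=int(getattr(r, "charge", 0) or 0),
                rt_start_s=float(r.rtStart) * 60.0,
                rt_apex_s=float(r.rtApex) * 60.0,
                rt_end_s=float(r.rtEnd) * 60.0,
                apex_intensity=float(r.intensityApex),
                n_isotopes=int(getattr(r, "nIsotopes", 1) or 1),
                n_scans=int(getattr(r, "nScans", 1) or 1),
            )
        )
    return out
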