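"""Independent plain-loop reference implementations used as oracles.

Everything here is deliberately written with dictionaries and explicit
loops, avoiding the vectorised code paths of the package, so agreement
is meaningful.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
import pandas as pd

from diaqc.report_io import PrecursorTable, RECORD_COLUMNS


def random_precursor_table(seed: int, n: int = 150) -> PrecursorTable:
    """A randomized PrecursorTable with 2-3 runs, 3 channels, shared
    peptides across groups, missing MS1 values and mixed q-values."""
    rng = np.random.default_rng(seed)
    n_runs = int(rng.integers(2, 4))
    runs = [f"run{i}" for i in range(n_runs)]
    n_pept = max(8, n // 6)
    peptides = [f"PEP{i}K" for i in range(n_pept)]
    proteins = {p: f"PR{i % max(2, n_pept // 3)}" for i, p in enumerate(peptides)}
    rows = []
    for _ in range(n):
        pep = peptides[int(rng.integers(0, n_pept))]
        ch = ["d0", "d4", "d8"][int(rng.integers(0, 3))]
        run = runs[int(rng.integers(0, n_runs))]
        charge = int(rng.integers(2, 4))
        ms1 = float(rng.lognormal(10, 1)) if rng.random() > 0.15 else np.nan
        rows.append(
            {
                "run_id": run,
                "modified_sequence": f"{pep}(mTRAQ-K-{ {'d0':0,'d4':4,'d8':8}[ch] })",
                "stripped_sequence": pep,
                "charge": charge,
                "precursor_mz": float(rng.uniform(380, 1400)),
                "protein_group": proteins[pep],
                "rt_seconds": float(rng.uniform(0, 1200)),
                "ms1_intensity": ms1,
                "ms2_intensity": float(rng.lognormal(11, 1)),
                "q_value": float(rng.uniform(0, 1) ** 2),
                "channel_q": np.nan,
                "translated_q": np.nan,
                "channel": ch,
                "translated": bool(rng.random() < 0.2),
            }
        )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df = df.drop_duplicates(["run_id", "modified_sequence", "charge"])
    return PrecursorTable(df=df)


def jaccard_loop(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    inter = sum(1 for x in a if x in b)
    union = len(a) + len(b) - inter
    return inter / union


def completeness_loop(table: PrecursorTable, by: str, id_key: str):
    """label-sorted dict-of-dicts of pairwise Jaccard indices."""
    col = "channel" if by == "channel" else "run_id"
    sets: dict[str, set] = {}
    for _, r in table.df.iterrows():
        key = (
            (r["stripped_sequence"], r["charge"])
            if id_key == "precursor"
            else r["protein_group"]
        )
        sets.setdefault(r[col], set()).add(key)
    labels = sorted(sets)
    return {
        a: {b: jaccard_loop(sets[a], sets[b]) for b in labels} for a in labels
    }


def cv_loop(table: PrecursorTable, min_peptides: int = 3):
    """(run, channel) -> median within-protein CV, via explicit dicts."""
    # peptide value per cell: sum of MS1 intensity over charges
    values: dict[tuple, float] = {}
    for _, r in table.df.iterrows():
        v = r["ms1_intensity"]
        if v is None or (isinstance(v, float) and math.isnan(v)) or v <= 0:
            continue
        key = (r["run_id"], r["channel"], r["protein_group"], r["stripped_sequence"])
        values[key] = values.get(key, 0.0) + float(v)
    # per-cell median normalisation
    by_cell: dict[tuple, list] = {}
    for (run, ch, prot, pep), v in values.items():
        by_cell.setdefault((run, ch), []).append(v)
    cell_median = {cell: statistics.median(v) for cell, v in by_cell.items()}
    values = {
        k: v / cell_median[(k[0], k[1])] for k, v in values.items()
    }
    # mean across cells per peptide
    totals: dict[tuple, list] = {}
    for (run, ch, prot, pep), v in values.items():
        totals.setdefault((prot, pep), []).append(v)
    means = {k: sum(v) / len(v) for k, v in totals.items()}
    rel = {k: v / means[(k[2], k[3])] for k, v in values.items()}
    # per-cell, per-protein CV
    by_cell_prot: dict[tuple, list] = {}
    for (run, ch, prot, pep), v in rel.items():
        by_cell_prot.setdefault((run, ch, prot), []).append(v)
    cvs: dict[tuple, list] = {}
    for (run, ch, prot), vals in sorted(by_cell_prot.items()):
        if len(vals) < min_peptides:
            continue
        m = statistics.fmean(vals)
        sd = statistics.stdev(vals)
        cvs.setdefault((run, ch), []).append(sd / m)
    return {cell: statistics.median(v) for cell, v in cvs.items()}


def fdr_counts_loop(q_values, thresholds):
    out = []
    for t in thresholds:
        out.append(sum(1 for q in q_values if q <= t))
    return out


def id_counts_loop(table: PrecursorTable, by: str, level: str):
    col = "run_id" if by == "run" else "channel"
    seen: dict[str, set] = {}
    for _, r in table.df.iterrows():
        key = (
            (r["modified_sequence"], r["charge"])
            if level == "precursor"
            else r["protein_group"]
        )
        seen.setdefault(r[col], set()).add(key)
    return {g: len(s) for g, s in seen.items()}


def tic_map_loop(scans, rt_edges, mz_edges):
    """Summed MS1 intensity per (RT bin, m/z bin) by explicit loops."""
    mat = np.zeros((len(rt_edges) - 1, len(mz_edges) - 1))
    for s in scans.ms1_scans():
        b = None
        for i in range(len(rt_edges) - 1):
            if rt_edges[i] <= s.rt_seconds < rt_edges[i + 1]:
                b = i
                break
        if b is None and s.rt_seconds == rt_edges[-1]:
            b = len(rt_edges) - 2
        if b is None:
            continue
        for mz, inten, _ in s.peaks():
            for j in range(len(mz_edges) - 1):
                if mz_edges[j] <= mz < mz_edges[j + 1]:
                    mat[b, j] += inten
                    break
    return mat


def detect_features_loop(scans, ppm_tol: float, min_scans: int,
                         gap_tolerance: int = 1):
    """Reference trace counter: greedy chaining with explicit loops,
    processing candidate matches closest-first per scan."""
    open_traces = []  # each: dict(mzs, rts, miss)
    closed = []
    for scan in scans.ms1_scans():
        peaks = list(scan.mz)
        used = [False] * len(peaks)
        matched = set()
        order = sorted(range(len(open_traces)),
                       key=lambda i: statistics.median(open_traces[i]["mzs"]))
        for ti in order:
            tr = open_traces[ti]
            med = statistics.median(tr["mzs"])
            tol = med * ppm_tol * 1e-6
            best, best_d = -1, tol
            for k, mz in enumerate(peaks):
                if used[k] and abs(mz - med) <= best_d:
                    continue
                if not used[k]:
                    d = abs(mz - med)
                    if d <= best_d:
                        best, best_d = k, d
            if best >= 0:
                used[best] = True
                tr["mzs"].append(peaks[best])
                tr["rts"].append(scan.rt_seconds)
                tr["miss"] = 0
                matched.add(ti)
        survivors = []
        for ti, tr in enumerate(open_traces):
            if ti in matched:
                survivors.append(tr)
            else:
                tr["miss"] += 1
                (closed if tr["miss"] > gap_tolerance else survivors).append(tr)
        for k, mz in enumerate(peaks):
            if not used[k]:
                survivors.append({"mzs": [mz], "rts": [scan.rt_seconds], "miss": 0})
        open_traces = survivors
    closed.extend(open_traces)
    return [t for t in closed if len(t["rts"]) >= min_scans]
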