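"""Synthetic 3-plex LC-MS run generator.

Produces a ScanTable, a DIA-NN-dialect PrecursorTable and ground-truth
tables for a multiplexed (mTRAQ d0/d4/d8) DIA experiment under an
explicit generative model, so every metric in the package can be tested
against known truth without any external data.

The model, in outline:

* Precursor m/z is drawn from a two-component log-normal mixture over
  the precursor range, concentrating density at low m/z the way tryptic
  peptide precursors do; abundance is log-normal over several decades;
  elution peaks are Gaussian with log-normally drawn widths.
* Each precursor elutes when the gradient's %B crosses a per-precursor
  hydrophobicity threshold drawn uniformly over the active ramp.
* Channels are copies of the same peptide shifted by the mTRAQ label
  spacing (4.0071 Da per label / charge) and scaled by a per-channel
  abundance factor; optional per-channel multiplicative peptide noise
  models degraded samples.
* Scans follow a duty-cycle schedule. Ion accumulation obeys the AGC
  law: injection time = min(maximum injection time, AGC target /
  instantaneous ion flux into the scan's m/z window), so crowded
  isolation windows fill in milliseconds while empty ones idle at the
  ceiling.
* The search-report emulation is phenomenological: a precursor is
  MS2-identified with probability increasing in its flux share within
  its isolation window at apex (a spectral-complexity proxy), is
  MS1-quantified iff some survey scan samples its peak above the limit
  of detection, and unidentified channel copies of an identified
  peptide become "translated" identifications with a set probability.
  It exists to exercise the metrics, not to model a search engine.
"""

from __future__ import annotations

import base64
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .dutycycle import DutyCycleSpec, scan_schedule, scan_time_ms
from .errors import ConfigError
from .report_io import PrecursorTable, RECORD_COLUMNS
from .scan_io import RunMetadata, ScanRecord, ScanTable

__all__ = [
    "MTRAQ_DELTA_DA",
    "GradientProfile",
    "ChannelSpec",
    "SimConfig",
    "SimResult",
    "gradient_percent_b",
    "time_at_percent_b",
    "simulate_run",
    "write_mzml",
]

MTRAQ_DELTA_DA = 4.0071  # mass spacing between adjacent mTRAQ channels
ISOTOPE_DA = 1.00335

_CHANNEL_LABEL_COUNT = {"d0": 0, "d4": 1, "d8": 2}


@dataclass(frozen=True)
class GradientProfile:
    """Piecewise-linear LC gradient: (time_min, percent buffer B) breakpoints."""

    breakpoints: tuple[tuple[float, float], ...]
    flow_note: str = ""

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(b)) for t, b in self.breakpoints)
        if len(pts) < 2:
            raise ConfigError("gradient needs at least two breakpoints")
        times = [t for t, _ in pts]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ConfigError("gradient breakpoint times must be non-decreasing")
        if any(not 0 <= b <= 100 for _, b in pts):
            raise ConfigError("percent B must be within [0, 100]")
        object.__setattr__(self, "breakpoints", pts)

    @property
    def span_min(self) -> tuple[float, float]:
        return self.breakpoints[0][0], self.breakpoints[-1][0]


#: 30-min active gradient (8-32 %B over min 3-33) at 200 nL/min, the
#: typical single-cell nano-LC profile this simulator emulates.
DEFAULT_GRADIENT = GradientProfile(
    breakpoints=(
        (0.0, 4.0),
        (2.5, 4.0),
        (3.0, 8.0),
        (33.0, 32.0),
        (34.0, 95.0),
        (35.0, 95.0),
        (35.1, 4.0),
        (53.0, 4.0),
    ),
    flow_note="200 nL/min",
)


def gradient_percent_b(profile: GradientProfile, t_min: float) -> float:
    """Percent buffer B at time t (minutes) by piecewise-linear interpolation."""
    lo, hi = profile.span_min
    if not lo <= t_min <= hi:
        raise ConfigError(f"t={t_min} min outside gradient span [{lo}, {hi}]")
    times = np.array([t for t, _ in profile.breakpoints])
    bs = np.array([b for _, b in profile.breakpoints])
    return float(np.interp(t_min, times, bs))


def time_at_percent_b(profile: GradientProfile, pct: float) -> float:
    """First time (minutes) the gradient reaches ``pct`` %B on an
    ascending segment."""
    pts = profile.breakpoints
    for (t0, b0), (t1, b1) in zip(pts, pts[1:]):
        if b1 > b0 and b0 <= pct <= b1:
            return t0 + (pct - b0) / (b1 - b0) * (t1 - t0)
    raise ConfigError(f"gradient never ramps through {pct} %B")


@dataclass(frozen=True)
class ChannelSpec:
    """One plexDIA channel: label, relative abundance, presence
    probability per precursor, and log-normal peptide-level noise sigma
    (0 = clean sample)."""

    label: str
    abundance_factor: float = 1.0
    presence_prob: float = 1.0
    peptide_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in _CHANNEL_LABEL_COUNT:
            raise ConfigError(f"channel label must be d0/d4/d8, got {self.label!r}")
        if not 0 <= self.presence_prob <= 1:
            raise ConfigError("presence_prob must be within [0, 1]")
        if self.abundance_factor <= 0:
            raise ConfigError("abundance_factor must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full generative description of one synthetic multiplexed run.

    Defaults emulate a 3-plex single-cell-scale experiment on a
    Q-Exactive-class instrument: 380-1400 Th precursor range, 3e6 AGC,
    log-normal abundances spanning roughly three decades, Gaussian
    elution peaks of ~2.5 s sigma on a 30-min active gradient.
    """

    seed: int
    run_id: str = "sim"
    n_precursors: int = 500
    mz_range: tuple[float, float] = (380.0, 1400.0)
    # (weight, log-mu, log-sigma) of the m/z offset above the range lower
    # edge; calibrated to put most precursors in the lower windows and to
    # leave the top isolation window nearly empty, as tryptic digests do
    mz_mixture: tuple[tuple[float, float, float], ...] = (
        (0.55, 5.45, 0.50),
        (0.45, 6.25, 0.22),
    )
    abundance_mu_log: float = math.log(2e7)
    abundance_sigma_log: float = 1.8
    sigma_mu_log: float = math.log(2.5)  # elution sigma (s), log-normal
    sigma_sigma_log: float = 0.35
    gradient: GradientProfile = DEFAULT_GRADIENT
    ramp_percent_b: tuple[float, float] = (8.0, 32.0)
    active_gradient_min: float = 30.0
    channels: tuple[ChannelSpec, ...] = (
        ChannelSpec("d0"),
        ChannelSpec("d4"),
        ChannelSpec("d8"),
    )
    charge_probs: tuple[tuple[int, float], ...] = ((2, 0.8), (3, 0.2))
    agc_target: float = 3e6
    max_injection_ms: float = 300.0
    noise_floor: float = 1e5  # baseline flux and per-peak noise level
    lod: float = 2e6  # limit of detection on per-scan sampled intensity
    isotope_ratios: tuple[float, ...] = (1.0, 0.5, 0.18)
    interference_threshold: float = 0.02
    p_translate: float = 0.75
    marginal_fraction: float = 0.15  # extra above-threshold rows for FDR curves
    decoy_feature_fraction: float = 0.2  # non-peptide contaminant traces
    mz_jitter_ppm: float = 2.0  # per-centroid mass-measurement noise
    peptides_per_protein: int = 5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_precursors < 0:
            raise ConfigError("n_precursors must be >= 0")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ConfigError("mz_range lower must be < upper")
        if not abs(sum(w for w, _, _ in self.mz_mixture) - 1.0) < 1e-9:
            raise ConfigError("mz_mixture weights must sum to 1")
        if not abs(sum(p for _, p in self.charge_probs) - 1.0) < 1e-9:
            raise ConfigError("charge_probs must sum to 1")
        for name in ("agc_target", "max_injection_ms", "noise_floor", "lod",
                     "active_gradient_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("p_translate", "marginal_fraction",
                     "decoy_feature_fraction", "interference_threshold"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be within [0, 1]")


@dataclass
class SimResult:
    """Everything one simulated acquisition produces."""

    scans: ScanTable
    report: PrecursorTable
    report_frame: pd.DataFrame  # raw DIA-NN-dialect rows as written to TSV
    truth_precursors: pd.DataFrame
    truth_features: pd.DataFrame
    config: SimConfig
    cycle: DutyCycleSpec

    def write_report_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.report_frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return path


# ---------------------------------------------------------------------------
# population draws


def _draw_sequences(rng: np.random.Generator, n: int) -> list[str]:
    """Unique random tryptic-looking peptide sequences ending in K."""
    alphabet = np.array(list("ACDEFGHILMNPQRSTVWY"))
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(8, 15))
        s = "".join(rng.choice(alphabet, size=length)) + "K"
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


def _draw_mz(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    lo, hi = cfg.mz_range
    weights = np.array([w for w, _, _ in cfg.mz_mixture])
    out = np.empty(n)
    for i in range(n):
        while True:
            k = rng.choice(len(weights), p=weights)
            _, mu, sig = cfg.mz_mixture[k]
            mz = lo + rng.lognormal(mu, sig)
            if mz < hi - 3 * MTRAQ_DELTA_DA:  # leave room for label offsets
                out[i] = mz
                break
    return out


def _modified_sequence(stripped: str, label: str) -> str:
    delta = _CHANNEL_LABEL_COUNT[label] * 4
    return f"{stripped[:-1]}K(mTRAQ-K-{delta})"


# ---------------------------------------------------------------------------
# the simulation proper


def simulate_run(config: SimConfig, cycle: DutyCycleSpec) -> SimResult:
    """Simulate one acquisition: scans, search report, ground truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_pop, rng_id, rng_noise, rng_scan = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    traces = _build_traces(config, rng_pop)
    schedule = _schedule_scans(config, cycle)
    scans, samples = _synthesise_scans(config, cycle, traces, schedule, rng_scan)
    truth_prec, report, report_frame = _emulate_report(
        config, cycle, traces, schedule, samples, rng_id, rng_noise
    )
    truth_feat = _truth_features(traces, samples, config)
    return SimResult(
        scans=scans,
        report=report,
        report_frame=report_frame,
        truth_precursors=truth_prec,
        truth_features=truth_feat,
        config=config,
        cycle=cycle,
    )


@dataclass
class _Traces:
    """Flat per-trace arrays; a trace is one channel copy of a precursor
    (or one contaminant)."""

    mz: np.ndarray
    z: np.ndarray
    apex_s: np.ndarray
    sigma_s: np.ndarray
    amp: np.ndarray
    precursor_idx: np.ndarray  # -1 for decoys
    channel_idx: np.ndarray  # -1 for decoys
    is_decoy: np.ndarray
    stripped: list[str]
    protein: list[str]
    n_isotopes: int

    @property
    def n(self) -> int:
        return len(self.mz)


def _build_traces(cfg: SimConfig, rng: np.random.Generator) -> _Traces:
    n = cfg.n_precursors
    seqs = _draw_sequences(rng, n)
    n_prot = max(1, n // cfg.peptides_per_protein)
    prot_of = rng.integers(0, n_prot, size=n)
    base_mz = _draw_mz(rng, cfg, n)
    charges = np.array([z for z, _ in cfg.charge_probs])
    probs = np.array([p for _, p in cfg.charge_probs])
    z = charges[rng.choice(len(charges), size=n, p=probs)]
    # elution: hydrophobicity surrogate = %B threshold along the ramp
    b0, b1 = cfg.ramp_percent_b
    thr = rng.uniform(b0 + 0.3, b1 - 0.3, size=n)
    t_start = time_at_percent_b(cfg.gradient, b0) * 60.0
    apex = np.array(
        [time_at_percent_b(cfg.gradient, t) * 60.0 for t in thr]
    )
    sigma = rng.lognormal(cfg.sigma_mu_log, cfg.sigma_sigma_log, size=n)
    abundance = rng.lognormal(cfg.abundance_mu_log, cfg.abundance_sigma_log, size=n)

    rows_mz, rows_z, rows_apex, rows_sigma, rows_amp = [], [], [], [], []
    rows_pidx, rows_cidx, rows_decoy, rows_seq, rows_prot = [], [], [], [], []
    for ci, ch in enumerate(cfg.channels):
        present = rng.random(n) < ch.presence_prob
        noise = (
            rng.lognormal(0.0, ch.peptide_noise_sigma, size=n)
            if ch.peptide_noise_sigma > 0
            else np.ones(n)
        )
        k = _CHANNEL_LABEL_COUNT[ch.label]
        for i in np.flatnonzero(present):
            rows_mz.append(base_mz[i] + MTRAQ_DELTA_DA * k / z[i])
            rows_z.append(z[i])
            rows_apex.append(apex[i])
            rows_sigma.append(sigma[i])
            rows_amp.append(abundance[i] * ch.abundance_factor * noise[i])
            rows_pidx.append(i)
            rows_cidx.append(ci)
            rows_decoy.append(False)
            rows_seq.append(seqs[i])
            rows_prot.append(f"PROT{prot_of[i]:04d}")
    # contaminant (decoy) traces: singly charged, low-m/z-biased, broader;
    # the configured fraction is of ALL ion traces (channel copies incl.)
    n_real = len(rows_mz)
    frac = cfg.decoy_feature_fraction
    n_decoy = int(round(frac / (1.0 - frac) * n_real)) if frac < 1 else 0
    lo, hi = cfg.mz_range
    duration = cfg.active_gradient_min * 60.0
    for _ in range(n_decoy):
        rows_mz.append(rng.uniform(lo + 5, min(hi - 5, 900.0)))
        rows_z.append(1)
        rows_apex.append(t_start + rng.uniform(0.05, 0.95) * duration)
        rows_sigma.append(
            rng.lognormal(cfg.sigma_mu_log + math.log(2.0), cfg.sigma_sigma_log)
        )
        rows_amp.append(rng.lognormal(cfg.abundance_mu_log, cfg.abundance_sigma_log))
        rows_pidx.append(-1)
        rows_cidx.append(-1)
        rows_decoy.append(True)
        rows_seq.append("")
        rows_prot.append("")
    return _Traces(
        mz=np.array(rows_mz, dtype=float),
        z=np.array(rows_z, dtype=int),
        apex_s=np.array(rows_apex, dtype=float),
        sigma_s=np.array(rows_sigma, dtype=float),
        amp=np.array(rows_amp, dtype=float),
        precursor_idx=np.array(rows_pidx, dtype=int),
        channel_idx=np.array(rows_cidx, dtype=int),
        is_decoy=np.array(rows_decoy, dtype=bool),
        stripped=rows_seq,
        protein=rows_prot,
        n_isotopes=len(cfg.isotope_ratios),
    )


def _schedule_scans(
    cfg: SimConfig, cycle: DutyCycleSpec
) -> pd.DataFrame:
    """Scan start times over the active gradient (whole cycles only)."""
    t_start = time_at_percent_b(cfg.gradient, cfg.ramp_percent_b[0]) * 60.0
    duration = cfg.active_gradient_min * 60.0
    per_scan_s = scan_time_ms(cycle) / 1000.0
    slots = scan_schedule(cycle)
    cycle_s = per_scan_s * len(slots)
    n_cycles = int(duration // cycle_s)
    rows = []
    idx = 1
    for c in range(n_cycles):
        base = t_start + c * cycle_s
        for slot, level, w in slots:
            rows.append(
                {
                    "scan_index": idx,
                    "rt_seconds": base + slot * per_scan_s,
                    "ms_level": level,
                    "window_index": -1 if w is None else w,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def _synthesise_scans(
    cfg: SimConfig,
    cycle: DutyCycleSpec,
    tr: _Traces,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[ScanTable, dict]:
    """Generate ScanRecords and per-trace MS1 sampling bookkeeping."""
    ratios = np.asarray(cfg.isotope_ratios)
    n_iso = len(ratios)
    if tr.n:
        iso_mz = tr.mz[:, None] + ISOTOPE_DA / tr.z[:, None] * np.arange(n_iso)
        iso_mz_flat = iso_mz.ravel()
        ratio_flat = np.tile(ratios, tr.n)
        trace_flat = np.repeat(np.arange(tr.n), n_iso)
    else:
        iso_mz_flat = np.empty(0)
        ratio_flat = np.empty(0)
        trace_flat = np.empty(0, dtype=int)
    windows = cycle.scheme.windows

    # per-trace MS1 sampling record: max sampled mono intensity, count of
    # above-LOD samples, first/last above-LOD sample times
    ms1_max = np.zeros(tr.n)
    ms1_n_above = np.zeros(tr.n, dtype=int)
    ms1_first = np.full(tr.n, np.nan)
    ms1_last = np.full(tr.n, np.nan)
    ms1_rts: list[float] = []

    records: list[ScanRecord] = []
    meta = RunMetadata(
        run_id=cfg.run_id,
        max_injection_ms=cycle.max_injection_ms,
        resolving_power=cycle.resolving_power,
        agc_target=cfg.agc_target,
        precursor_range=cfg.mz_range,
    )
    for row in schedule.itertuples():
        t = row.rt_seconds
        if tr.n:
            g = tr.amp * np.exp(
                -((t - tr.apex_s) ** 2) / (2.0 * tr.sigma_s**2)
            )
            inten_flat = g[trace_flat] * ratio_flat
        else:
            g = np.empty(0)
            inten_flat = np.empty(0)
        if row.ms_level == 1:
            flux = float(inten_flat.sum()) + cfg.noise_floor
            inj = min(cycle.max_injection_ms, 1000.0 * cfg.agc_target / flux)
            above = inten_flat >= cfg.lod
            mz_peaks = iso_mz_flat[above]
            if cfg.mz_jitter_ppm > 0 and len(mz_peaks):
                mz_peaks = mz_peaks * (
                    1.0 + rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6, len(mz_peaks))
                )
            order = np.argsort(mz_peaks)
            rec = ScanRecord(
                scan_index=int(row.scan_index),
                ms_level=1,
                rt_seconds=t,
                injection_time_ms=inj,
                tic=flux,
                mz=mz_peaks[order],
                intensity=inten_flat[above][order],
                noise=np.full(int(above.sum()), cfg.noise_floor),
            )
            # mono-isotope sampling bookkeeping
            if tr.n:
                mono_above = g >= cfg.lod
                ms1_max = np.maximum(ms1_max, g)
                ms1_n_above += mono_above
                newly = mono_above & np.isnan(ms1_first)
                ms1_first[newly] = t
                ms1_last[mono_above] = t
            ms1_rts.append(t)
        else:
            lo, hi = windows[row.window_index]
            in_win = (iso_mz_flat >= lo) & (iso_mz_flat < hi)
            flux = float(inten_flat[in_win].sum()) + cfg.noise_floor
            inj = min(cycle.max_injection_ms, 1000.0 * cfg.agc_target / flux)
            rec = ScanRecord(
                scan_index=int(row.scan_index),
                ms_level=2,
                rt_seconds=t,
                injection_time_ms=inj,
                tic=flux,
                isolation_center_mz=(lo + hi) / 2.0,
                isolation_width_mz=hi - lo,
                mz=np.empty(0),
                intensity=np.empty(0),
            )
        records.append(rec)
    samples = {
        "ms1_max": ms1_max,
        "ms1_n_above": ms1_n_above,
        "ms1_first": ms1_first,
        "ms1_last": ms1_last,
        "ms1_rts": np.array(ms1_rts),
        "schedule": schedule,
    }
    return ScanTable(metadata=meta, scans=records), samples


def _window_flux_at_apex(
    cfg: SimConfig, cycle: DutyCycleSpec, tr: _Traces
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trace isolation-window index and own-flux share at apex."""
    windows = cycle.scheme.windows
    edges = np.array([w[0] for w in windows] + [windows[-1][1]])
    win_idx = np.searchsorted(edges, tr.mz, side="right") - 1
    win_idx = np.clip(win_idx, 0, len(windows) - 1)
    ratios = np.asarray(cfg.isotope_ratios)
    n_iso = len(ratios)
    iso_mz_flat = (
        tr.mz[:, None] + ISOTOPE_DA / tr.z[:, None] * np.arange(n_iso)
    ).ravel()
    ratio_flat = np.tile(ratios, tr.n)
    trace_flat = np.repeat(np.arange(tr.n), n_iso)
    win_masks = [
        (iso_mz_flat >= lo) & (iso_mz_flat < hi) for lo, hi in windows
    ]
    share = np.zeros(tr.n)
    for i in range(tr.n):
        t = tr.apex_s[i]
        g = tr.amp * np.exp(-((t - tr.apex_s) ** 2) / (2.0 * tr.sigma_s**2))
        inten_flat = g[trace_flat] * ratio_flat
        mask = win_masks[win_idx[i]]
        total = float(inten_flat[mask].sum()) + cfg.noise_floor
        own = float(inten_flat[mask & (trace_flat == i)].sum())
        share[i] = own / total
    return win_idx, share


def _emulate_report(
    cfg: SimConfig,
    cycle: DutyCycleSpec,
    tr: _Traces,
    schedule: pd.DataFrame,
    samples: dict,
    rng_id: np.random.Generator,
    rng_noise: np.random.Generator,
) -> tuple[pd.DataFrame, PrecursorTable, pd.DataFrame]:
    real = ~tr.is_decoy
    idx_real = np.flatnonzero(real)
    win_idx = np.full(tr.n, -1)
    share = np.zeros(tr.n)
    if tr.n:
        win_idx, share = _window_flux_at_apex(cfg, cycle, tr)

    # direct identification: flux-share interference model
    p_id = np.minimum(1.0, share / cfg.interference_threshold)
    p_id[tr.amp < cfg.lod] = 0.0  # undetectably low signal
    direct = (rng_id.random(tr.n) < p_id) & real

    # translated: unidentified channel copies of an identified peptide
    ident_precursors = set(tr.precursor_idx[direct])
    can_translate = (
        real
        & ~direct
        & (tr.amp >= cfg.lod)
        & np.isin(tr.precursor_idx, list(ident_precursors))
    )
    translated = can_translate & (rng_id.random(tr.n) < cfg.p_translate)

    ms1_max = samples["ms1_max"]
    ms1_sampled = samples["ms1_n_above"] > 0
    # S/N truth at the MS1 scan nearest the apex
    ms1_rts = samples["ms1_rts"]
    if len(ms1_rts) and tr.n:
        nearest = np.searchsorted(ms1_rts, tr.apex_s)
        nearest = np.clip(nearest, 0, len(ms1_rts) - 1)
        left = np.clip(nearest - 1, 0, len(ms1_rts) - 1)
        pick = np.where(
            np.abs(ms1_rts[left] - tr.apex_s) <= np.abs(ms1_rts[nearest] - tr.apex_s),
            left,
            nearest,
        )
        t_near = ms1_rts[pick]
        g_near = tr.amp * np.exp(
            -((t_near - tr.apex_s) ** 2) / (2.0 * tr.sigma_s**2)
        )
    else:
        g_near = np.zeros(tr.n)

    channels = cfg.channels
    truth = pd.DataFrame(
        {
            "trace_index": np.arange(tr.n),
            "precursor_index": tr.precursor_idx,
            "channel": [
                channels[c].label if c >= 0 else "" for c in tr.channel_idx
            ],
            "stripped_sequence": tr.stripped,
            "protein_group": tr.protein,
            "charge": tr.z,
            "mz": tr.mz,
            "apex_rt_s": tr.apex_s,
            "sigma_s": tr.sigma_s,
            "amp": tr.amp,
            "window_index": win_idx,
            "flux_share": share,
            "identified_direct": direct,
            "translated": translated,
            "ms1_sampled": ms1_sampled,
            "ms1_max_sample": ms1_max,
            "sn_nearest_ms1": g_near / cfg.noise_floor,
            "is_decoy": tr.is_decoy,
        }
    )

    # emitted report rows
    rows = []
    emitted = np.flatnonzero(direct | translated)
    for i in emitted:
        ch = channels[tr.channel_idx[i]]
        modseq = _modified_sequence(tr.stripped[i], ch.label)
        q = 10.0 ** rng_noise.uniform(-5.0, -2.2)
        if direct[i]:
            channel_q = 10.0 ** rng_noise.uniform(-5.0, -2.2)
            translated_q = channel_q
        else:
            channel_q = 10.0 ** rng_noise.uniform(-1.8, -0.5)
            translated_q = 10.0 ** rng_noise.uniform(-5.0, -2.2)
        ms1_val = ms1_max[i] if ms1_sampled[i] else np.nan
        rows.append(
            {
                "Run": cfg.run_id,
                "Modified.Sequence": modseq,
                "Stripped.Sequence": tr.stripped[i],
                "Precursor.Charge": tr.z[i],
                "Precursor.Mz": tr.mz[i],
                "Protein.Group": tr.protein[i],
                "RT": tr.apex_s[i] / 60.0,
                "Ms1.Area": ms1_val,
                "Precursor.Quantity": max(g_near[i], cfg.noise_floor),
                "Q.Value": q,
                "Channel.Q.Value": channel_q,
                "Translated.Q.Value": translated_q,
            }
        )
    # marginal rows above the usual identification threshold (FDR-curve fodder)
    n_marginal = int(round(cfg.marginal_fraction * len(emitted)))
    lo, hi = cfg.mz_range
    t_start = time_at_percent_b(cfg.gradient, cfg.ramp_percent_b[0]) * 60.0
    marg_seqs = _draw_sequences(rng_noise, n_marginal)
    for j in range(n_marginal):
        ch = channels[int(rng_noise.integers(0, len(channels)))]
        seq = marg_seqs[j]
        q = 10.0 ** rng_noise.uniform(-1.95, 0.0)
        rows.append(
            {
                "Run": cfg.run_id,
                "Modified.Sequence": _modified_sequence(seq, ch.label),
                "Stripped.Sequence": seq,
                "Precursor.Charge": 2,
                "Precursor.Mz": rng_noise.uniform(lo, hi),
                "Protein.Group": f"MARG{j:04d}",
                "RT": (t_start + rng_noise.uniform(0, cfg.active_gradient_min * 60))
                / 60.0,
                "Ms1.Area": np.nan,
                "Precursor.Quantity": cfg.noise_floor,
                "Q.Value": q,
                "Channel.Q.Value": q,
                "Translated.Q.Value": np.nan,
            }
        )
    report_df = pd.DataFrame(
        rows,
        columns=[
            "Run",
            "Modified.Sequence",
            "Stripped.Sequence",
            "Precursor.Charge",
            "Precursor.Mz",
            "Protein.Group",
            "RT",
            "Ms1.Area",
            "Precursor.Quantity",
            "Q.Value",
            "Channel.Q.Value",
            "Translated.Q.Value",
        ],
    )
    table = _report_frame_to_table(report_df, cfg.run_id)
    return truth, table, report_df


def _report_frame_to_table(report_df: pd.DataFrame, run_id: str) -> PrecursorTable:
    """Build the in-memory PrecursorTable equivalent of the emitted report
    (unfiltered; reading the TSV through report_io applies q-filtering)."""
    from .report_io import parse_channel

    if report_df.empty:
        df = pd.DataFrame(columns=RECORD_COLUMNS)
        return PrecursorTable(df=df, runs=[run_id])
    df = pd.DataFrame(
        {
            "run_id": report_df["Run"],
            "modified_sequence": report_df["Modified.Sequence"],
            "stripped_sequence": report_df["Stripped.Sequence"],
            "charge": report_df["Precursor.Charge"].astype(int),
            "precursor_mz": report_df["Precursor.Mz"].astype(float),
            "protein_group": report_df["Protein.Group"],
            "rt_seconds": report_df["RT"].astype(float) * 60.0,
            "ms1_intensity": report_df["Ms1.Area"].astype(float),
            "ms2_intensity": report_df["Precursor.Quantity"].astype(float),
            "q_value": report_df["Q.Value"].astype(float),
            "channel_q": report_df["Channel.Q.Value"].astype(float),
            "translated_q": report_df["Translated.Q.Value"].astype(float),
        }
    )
    df["channel"] = df["modified_sequence"].map(parse_channel)
    direct_q = df["channel_q"].where(df["channel_q"].notna(), df["q_value"])
    df["translated"] = (
        df["translated_q"].notna()
        & (df["translated_q"] <= 0.01)
        & (direct_q > 0.01)
    )
    return PrecursorTable(df=df[RECORD_COLUMNS], runs=[run_id])


def _truth_features(tr: _Traces, samples: dict, cfg: SimConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trace_index": np.arange(tr.n),
            "mz": tr.mz,
            "charge": tr.z,
            "apex_rt_s": tr.apex_s,
            "sigma_s": tr.sigma_s,
            "amp": tr.amp,
            "n_ms1_above_lod": samples["ms1_n_above"],
            "rt_first_above_lod": samples["ms1_first"],
            "rt_last_above_lod": samples["ms1_last"],
            "is_decoy": tr.is_decoy,
        }
    )


def truth_as_precursor_table(result: SimResult) -> PrecursorTable:
    """Ground-truth traces recast as a PrecursorTable (all real traces,
    identified or not) for oracle comparisons, e.g. feature matching."""
    t = result.truth_precursors
    t = t[~t["is_decoy"]]
    df = pd.DataFrame(
        {
            "run_id": result.config.run_id,
            "modified_sequence": [
                _modified_sequence(s, c)
                for s, c in zip(t["stripped_sequence"], t["channel"])
            ],
            "stripped_sequence": t["stripped_sequence"].to_numpy(),
            "charge": t["charge"].to_numpy(),
            "precursor_mz": t["mz"].to_numpy(),
            "protein_group": t["protein_group"].to_numpy(),
            "rt_seconds": t["apex_rt_s"].to_numpy(),
            "ms1_intensity": t["ms1_max_sample"].to_numpy(),
            "ms2_intensity": np.nan,
            "q_value": 0.0,
            "channel_q": 0.0,
            "translated_q": np.nan,
            "channel": t["channel"].to_numpy(),
            "translated": False,
        }
    )
    return PrecursorTable(df=df[RECORD_COLUMNS], runs=[result.config.run_id])


__all__.append("truth_as_precursor_table")


# ---------------------------------------------------------------------------
# minimal mzML writing


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


_MZML_NS = "http://psi.hupo.org/ms/mzml"


def write_mzml(scans: ScanTable, path: str | Path) -> Path:
    """Write a ScanTable as minimal centroid mzML 1.1.

    Emits per spectrum: MS level, centroid flag, total ion current, scan
    start time (minutes), ion injection time, the isolation window for
    MS2 scans, and 64-bit uncompressed m/z / intensity arrays plus a
    per-peak noise array when present. Run metadata is stored as
    userParams on the <run> element so a round trip through
    :func:`diaqc.scan_io.read_mzml_scans` is lossless.
    """
    path = Path(path)
    root = etree.Element("mzML", nsmap={None: _MZML_NS}, version="1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cv_list, "cv", id="MS", fullName="Proteomics Standards Initiative Mass "
        "Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cv_list, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/"
        "unit-ontology/master/unit.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")

    meta = scans.metadata
    run = etree.SubElement(root, "run", id=meta.run_id)
    for name, value in (
        ("diaqc:max_injection_ms", repr(meta.max_injection_ms)),
        ("diaqc:resolving_power", str(meta.resolving_power)),
        ("diaqc:agc_target", repr(meta.agc_target)),
        ("diaqc:precursor_range_lower", repr(meta.precursor_range[0])),
        ("diaqc:precursor_range_upper", repr(meta.precursor_range[1])),
    ):
        etree.SubElement(run, "userParam", name=name, value=value)
    slist = etree.SubElement(run, "spectrumList", count=str(len(scans)))

    for i, rec in enumerate(scans):
        mz = rec.mz if rec.mz is not None else np.empty(0)
        inten = rec.intensity if rec.intensity is not None else np.empty(0)
        spec = etree.SubElement(
            slist,
            "spectrum",
            index=str(i),
            id=f"scan={rec.scan_index}",
            defaultArrayLength=str(len(mz)),
        )
        _cv(spec, "MS:1000511", "ms level", str(rec.ms_level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        _cv(
            spec, "MS:1000579" if rec.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if rec.ms_level == 1 else "MSn spectrum",
        )
        _cv(spec, "MS:1000285", "total ion current", repr(rec.tic))
        sl = etree.SubElement(spec, "scanList", count="1")
        _cv(sl, "MS:1000795", "no combination")
        scan = etree.SubElement(sl, "scan")
        _cv(
            scan, "MS:1000016", "scan start time", repr(rec.rt_seconds / 60.0),
            unit=("UO:0000031", "minute"),
        )
        if not math.isnan(rec.injection_time_ms):
            _cv(
                scan, "MS:1000927", "ion injection time",
                repr(rec.injection_time_ms),
                unit=("UO:0000028", "millisecond"),
            )
        if rec.ms_level == 2 and not math.isnan(rec.isolation_center_mz):
            plist = etree.SubElement(spec, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            iso = etree.SubElement(prec, "isolationWindow")
            _cv(
                iso, "MS:1000827", "isolation window target m/z",
                repr(rec.isolation_center_mz),
            )
            if not math.isnan(rec.isolation_width_mz):
                half = rec.isolation_width_mz / 2.0
                _cv(iso, "MS:1000828", "isolation window lower offset", repr(half))
                _cv(iso, "MS:1000829", "isolation window upper offset", repr(half))
        arrays = [("MS:1000514", "m/z array", mz), ("MS:1000515", "intensity array", inten)]
        if rec.noise is not None:
            arrays.append(("MS:1000786", "non-standard data array", rec.noise))
        balist = etree.SubElement(
            spec, "binaryDataArrayList", count=str(len(arrays))
        )
        for acc, name, arr in arrays:
            encoded = _b64(arr)
            ba = etree.SubElement(
                balist, "binaryDataArray", encodedLength=str(len(encoded))
            )
            _cv(ba, "MS:1000523", "64-bit float")
            _cv(ba, "MS:1000576", "no compression")
            if acc == "MS:1000786":
                _cv(ba, acc, name, "noise array")
            else:
                _cv(ba, acc, name)
            etree.SubElement(ba, "binary").text = encoded

    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )
    return path


def _cv(
    parent, accession: str, name: str, value: str = "",
    unit: tuple[str, str] | None = None,
) -> None:
    attrs = {"cvRef": accession.split(":")[0], "accession": accession,
             "name": name, "value": value}
    if unit is not None:
        attrs["unitCvRef"] = unit[0].split(":")[0]
        attrs["unitAccession"] = unit[0]
        attrs["unitName"] = unit[1]
    etree.SubElement(parent, "cvParam", **attrs)
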