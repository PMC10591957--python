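"""Per-scan acquisition metadata: mzML reading and TSV caching.

The substrate for all instrument-level metrics is one record per scan
holding MS level, retention time, ion injection (accumulation) time,
total ion current, the MS2 isolation window, and optionally the
centroided peak list with per-peak noise estimates.

mzML parsing is a small streaming reader built on lxml's iterparse; it
handles exactly the subset of mzML 1.1 this package consumes (spectrum
cvParams, scan start time with unit accession, ion injection time,
isolation windows, uncompressed or zlib 32/64-bit float binary arrays)
and keeps memory flat over arbitrarily long runs. Retention times are
normalised to seconds internally regardless of the unit declared in the
file.
"""

from __future__ import annotations

import base64
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .errors import FormatError, SchemaError, UnsupportedScanLevelError

log = logging.getLogger(__name__)

__all__ = [
    "RunMetadata",
    "ScanRecord",
    "ScanTable",
    "read_mzml_scans",
    "write_scan_table",
    "read_scan_table",
]

SCAN_COLUMNS = [
    "scan_index",
    "ms_level",
    "rt_seconds",
    "injection_time_ms",
    "tic",
    "isolation_center_mz",
    "isolation_width_mz",
]


@dataclass(frozen=True)
class RunMetadata:
    """Instrument settings of one acquisition run.

    Defaults are typical Q-Exactive DIA settings (70k resolving power,
    3e6 AGC target, 300 ms maximum accumulation, 380-1400 Th precursor
    range); plain mzML does not carry these, so callers reading vendor
    conversions should pass the real values.
    """

    run_id: str = "run"
    max_injection_ms: float = 300.0
    resolving_power: int = 70000
    agc_target: float = 3e6
    precursor_range: tuple[float, float] = (380.0, 1400.0)

    def __post_init__(self) -> None:
        lo, hi = self.precursor_range
        if not lo < hi:
            raise SchemaError("precursor_range lower must be < upper")
        if self.max_injection_ms <= 0 or self.resolving_power <= 0:
            raise SchemaError("timing settings must be positive")


@dataclass
class ScanRecord:
    """One spectrum's acquisition metadata plus optional centroid peaks.

    Missing values (injection time not reported, MS1 isolation fields,
    absent noise array) are NaN / None, never zero.
    """

    scan_index: int  # 1-based
    ms_level: int
    rt_seconds: float
    injection_time_ms: float = math.nan
    tic: float = 0.0
    isolation_center_mz: float = math.nan
    isolation_width_mz: float = math.nan
    mz: np.ndarray | None = None
    intensity: np.ndarray | None = None
    noise: np.ndarray | None = None

    @property
    def peaks_loaded(self) -> bool:
        return self.mz is not None

    def peaks(self) -> list[tuple[float, float, float]]:
        """Peaks as (mz, intensity, noise) tuples; noise NaN when absent."""
        if self.mz is None:
            return []
        noise = (
            self.noise
            if self.noise is not None
            else np.full(len(self.mz), math.nan)
        )
        return list(zip(self.mz.tolist(), self.intensity.tolist(), noise.tolist()))


@dataclass
class ScanTable:
    """Ordered per-scan records of one run, with run metadata."""

    metadata: RunMetadata
    scans: list[ScanRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)

    def ms1_scans(self) -> list[ScanRecord]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2_scans(self) -> list[ScanRecord]:
        return [s for s in self.scans if s.ms_level == 2]

    def frame(self) -> pd.DataFrame:
        """Scalar fields as a DataFrame (one row per scan)."""
        return pd.DataFrame(
            {
                "scan_index": [s.scan_index for s in self.scans],
                "ms_level": [s.ms_level for s in self.scans],
                "rt_seconds": [s.rt_seconds for s in self.scans],
                "injection_time_ms": [s.injection_time_ms for s in self.scans],
                "tic": [s.tic for s in self.scans],
                "isolation_center_mz": [s.isolation_center_mz for s in self.scans],
                "isolation_width_mz": [s.isolation_width_mz for s in self.scans],
            }
        )

    def validate(self) -> list[str]:
        """Invariant violations; empty list when the table is consistent."""
        out: list[str] = []
        prev_rt = -math.inf
        for s in self.scans:
            if s.ms_level not in (1, 2):
                out.append(f"scan {s.scan_index}: ms_level {s.ms_level}")
            if s.rt_seconds < prev_rt - 1e-9:
                out.append(f"scan {s.scan_index}: RT decreases")
            prev_rt = s.rt_seconds
            if s.tic < 0:
                out.append(f"scan {s.scan_index}: negative TIC")
            if s.ms_level == 1 and not math.isnan(s.isolation_center_mz):
                out.append(f"scan {s.scan_index}: MS1 with isolation window")
            if s.mz is not None and len(s.mz) > 1 and np.any(np.diff(s.mz) <= 0):
                out.append(f"scan {s.scan_index}: peaks not sorted by m/z")
        if self.ms2_scans() and not self.ms1_scans():
            out.append("MS2 scans present without any MS1 scan")
        return out


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _children(elem, name: str):
    return [c for c in elem if _local(c.tag) == name]


def _cv_map(elem) -> dict[str, tuple[str, dict]]:
    """accession -> (value, attributes) for direct cvParam children."""
    out = {}
    for c in _children(elem, "cvParam"):
        out[c.get("accession", "")] = (c.get("value", ""), dict(c.attrib))
    return out


_RT_UNIT_FACTORS = {
    "UO:0000010": 1.0,  # second
    "UO:0000031": 60.0,  # minute
    "UO:0000032": 3600.0,  # hour
}

_DTYPES = {"MS:1000523": "<f8", "MS:1000521": "<f4"}


def _decode_binary(ba) -> tuple[str | None, np.ndarray]:
    """Decode one binaryDataArray element: (array kind, values)."""
    cvs = _cv_map(ba)
    dtype = next((d for acc, d in _DTYPES.items() if acc in cvs), "<f8")
    compressed = "MS:1000574" in cvs  # zlib
    if "MS:1000514" in cvs:
        kind = "mz"
    elif "MS:1000515" in cvs:
        kind = "intensity"
    elif "MS:1000786" in cvs:  # non-standard data array, named by its value
        kind = cvs["MS:1000786"][0] or "non-standard"
    else:
        kind = None
    binary = _children(ba, "binary")
    text = binary[0].text if binary and binary[0].text else ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_scans(
    path: str | Path,
    load_peaks: bool = True,
    metadata: RunMetadata | None = None,
) -> ScanTable:
    """Read per-scan acquisition metadata from an mzML file.

    One ScanRecord per spectrum, in file order. RT is converted to
    seconds honouring the unit accession (assuming minutes, with a
    warning, when no unit is declared — the common Thermo convention).
    TIC comes from the file's "total ion current" cvParam when present,
    else is computed as the sum of centroid intensities. When
    ``load_peaks`` is false, peak arrays are dropped after TIC
    determination. Run metadata is read from userParams on the <run>
    element if present (as written by :func:`diaqc.simulate.write_mzml`),
    else Q-Exactive-style defaults apply.
    """
    path = Path(path)
    records: list[ScanRecord] = []
    meta_fields: dict[str, object] = {}
    run_id = path.stem if path.suffix else str(path)
    in_run = False
    try:
        for event, elem in etree.iterparse(
            str(path), events=("start", "end"), huge_tree=True
        ):
            tag = _local(elem.tag)
            if event == "start":
                if tag == "run":
                    in_run = True
                    run_id = elem.get("id", run_id)
                continue
            if tag == "userParam" and in_run:
                name = elem.get("name", "")
                if name in _META_PARAMS:
                    key, cast = _META_PARAMS[name]
                    meta_fields[key] = cast(elem.get("value"))
            elif tag == "spectrum":
                records.append(
                    _spectrum_to_record(elem, len(records) + 1, load_peaks)
                )
                elem.clear()
                while elem.getprevious() is not None:
                    del elem.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"unparseable mzML {path}: {exc}") from exc
    if metadata is None:
        lo = meta_fields.pop("_lo", 380.0)
        hi = meta_fields.pop("_hi", 1400.0)
        metadata = RunMetadata(
            run_id=run_id, precursor_range=(float(lo), float(hi)),
            **meta_fields,  # type: ignore[arg-type]
        )
    return ScanTable(metadata=metadata, scans=records)


def _spectrum_to_record(elem, index: int, load_peaks: bool) -> ScanRecord:
    cvs = _cv_map(elem)
    level_val = cvs.get("MS:1000511", ("", {}))[0]
    level = int(level_val) if level_val else -1
    if level not in (1, 2):
        raise UnsupportedScanLevelError(
            f"spectrum {elem.get('id', index)}: ms level {level_val!r} unsupported"
        )

    rt = math.nan
    inj_ms = math.nan
    for slist in _children(elem, "scanList"):
        for scan in _children(slist, "scan"):
            scvs = _cv_map(scan)
            if "MS:1000016" in scvs:
                value, attrs = scvs["MS:1000016"]
                unit = attrs.get("unitAccession")
                factor = _RT_UNIT_FACTORS.get(unit)
                if factor is None:
                    if unit is None:
                        log.warning(
                            "scan start time without unit accession; "
                            "assuming minutes"
                        )
                    factor = 60.0
                rt = float(value) * factor
            if "MS:1000927" in scvs:
                inj_ms = float(scvs["MS:1000927"][0])

    center = width = math.nan
    if level == 2:
        for plist in _children(elem, "precursorList"):
            for prec in _children(plist, "precursor"):
                for iso in _children(prec, "isolationWindow"):
                    icvs = _cv_map(iso)
                    if "MS:1000827" in icvs:
                        center = float(icvs["MS:1000827"][0])
                    if "MS:1000828" in icvs and "MS:1000829" in icvs:
                        width = float(icvs["MS:1000828"][0]) + float(
                            icvs["MS:1000829"][0]
                        )

    arrays: dict[str, np.ndarray] = {}
    for balist in _children(elem, "binaryDataArrayList"):
        for ba in _children(balist, "binaryDataArray"):
            kind, values = _decode_binary(ba)
            if kind:
                arrays[kind] = values

    inten = arrays.get("intensity")
    if "MS:1000285" in cvs:
        tic = float(cvs["MS:1000285"][0])
    else:
        tic = float(inten.sum()) if inten is not None and len(inten) else 0.0
    rec = ScanRecord(
        scan_index=index,
        ms_level=level,
        rt_seconds=rt,
        injection_time_ms=inj_ms,
        tic=tic,
        isolation_center_mz=center,
        isolation_width_mz=width,
    )
    if load_peaks and "mz" in arrays:
        rec.mz = arrays["mz"]
        rec.intensity = inten if inten is not None else np.zeros(len(rec.mz))
        noise = arrays.get("noise array")
        if noise is not None:
            rec.noise = noise
    return rec


_META_PARAMS = {
    "diaqc:max_injection_ms": ("max_injection_ms", float),
    "diaqc:resolving_power": ("resolving_power", int),
    "diaqc:agc_target": ("agc_target", float),
    "diaqc:precursor_range_lower": ("_lo", float),
    "diaqc:precursor_range_upper": ("_hi", float),
}


def write_scan_table(
    table: ScanTable, path: str | Path, peaks_sidecar: bool = False
) -> Path:
    """Write a ScanTable as TSV; run metadata goes into '#key=value' header
    lines. Peaks are optionally stored in a ``<path>.peaks.tsv`` sidecar."""
    path = Path(path)
    meta = table.metadata
    lines = [
        f"#run_id={meta.run_id}",
        f"#max_injection_ms={meta.max_injection_ms!r}",
        f"#resolving_power={meta.resolving_power}",
        f"#agc_target={meta.agc_target!r}",
        f"#precursor_range={meta.precursor_range[0]!r},{meta.precursor_range[1]!r}",
    ]
    frame = table.frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    if peaks_sidecar:
        rows = []
        for s in table.scans:
            if s.mz is None:
                continue
            noise = s.noise if s.noise is not None else np.full(len(s.mz), np.nan)
            for m, i, nz in zip(s.mz, s.intensity, noise):
                rows.append((s.scan_index, m, i, nz))
        pd.DataFrame(
            rows, columns=["scan_index", "mz", "intensity", "noise"]
        ).to_csv(
            path.with_suffix(path.suffix + ".peaks.tsv"),
            sep="\t",
            index=False,
            float_format="%.17g",
        )
    return path


def read_scan_table(path: str | Path, load_peaks: bool = False) -> ScanTable:
    """Read a TSV scan table written by :func:`write_scan_table`."""
    path = Path(path)
    meta_fields: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].rstrip("\n").partition("=")
                meta_fields[key] = value
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        frame = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    for col in SCAN_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"scan table {path} missing column '{col}'")
    meta = _metadata_from_strings(meta_fields)
    records = [
        ScanRecord(
            scan_index=int(r.scan_index),
            ms_level=int(r.ms_level),
            rt_seconds=float(r.rt_seconds),
            injection_time_ms=float(r.injection_time_ms),
            tic=float(r.tic),
            isolation_center_mz=float(r.isolation_center_mz),
            isolation_width_mz=float(r.isolation_width_mz),
        )
        for r in frame.itertuples()
    ]
    table = ScanTable(metadata=meta, scans=records)
    if load_peaks:
        side = path.with_suffix(path.suffix + ".peaks.tsv")
        if side.exists():
            _attach_peaks(table, side)
    return table


def _metadata_from_strings(fields: dict[str, str]) -> RunMetadata:
    if not fields:
        return RunMetadata()
    try:
        lo, hi = fields.get("precursor_range", "380,1400").split(",")
        return RunMetadata(
            run_id=fields.get("run_id", "run"),
            max_injection_ms=float(fields.get("max_injection_ms", 300.0)),
            resolving_power=int(fields.get("resolving_power", 70000)),
            agc_target=float(fields.get("agc_target", 3e6)),
            precursor_range=(float(lo), float(hi)),
        )
    except ValueError as exc:
        raise SchemaError(f"malformed metadata header: {exc}") from exc


def _attach_peaks(table: ScanTable, sidecar: Path) -> None:
    frame = pd.read_csv(sidecar, sep="\t", float_precision="round_trip")
    by_scan = dict(tuple(frame.groupby("scan_index")))
    for rec in table.scans:
        sub = by_scan.get(rec.scan_index)
        if sub is None:
            continue
        rec.mz = sub["mz"].to_numpy(float)
        rec.intensity = sub["intensity"].to_numpy(float)
        noise = sub["noise"].to_numpy(float)
        rec.noise = None if np.all(np.isnan(noise)) else noise
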