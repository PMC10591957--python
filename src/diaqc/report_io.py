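"""DIA-NN-dialect search-report parsing with plexDIA channel annotation.

A report row is one precursor x run x channel observation. Channels of
a multiplexed (plexDIA) set are encoded in the modified sequence as
mTRAQ label tags; non-isobaric labels shift the precursor mass, so each
channel is a separate precursor entry for the search engine. Besides the
run-wide q-value, plexDIA reports may carry a channel-specific q-value
and a "translated" q-value for identifications propagated from another
channel of the same set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AmbiguousChannelError, SchemaError

log = logging.getLogger(__name__)

__all__ = [
    "CHANNELS",
    "PrecursorRecord",
    "PrecursorTable",
    "parse_channel",
    "strip_sequence",
    "read_report",
]

CHANNELS = ("d0", "d4", "d8", "unlabeled")

#: canonical column -> accepted report-header spellings, first match wins
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "run_id": ("Run",),
    "modified_sequence": ("Modified.Sequence",),
    "stripped_sequence": ("Stripped.Sequence",),
    "charge": ("Precursor.Charge",),
    "precursor_mz": ("Precursor.Mz",),
    "protein_group": ("Protein.Group",),
    "rt_minutes": ("RT",),
    "ms1_intensity": ("Ms1.Area", "Ms1.Translated"),
    "ms2_intensity": ("Precursor.Quantity", "Precursor.Translated"),
    "q_value": ("Q.Value",),
    "channel_q": ("Channel.Q.Value",),
    "translated_q": ("Translated.Q.Value",),
}

MANDATORY = (
    "run_id",
    "modified_sequence",
    "charge",
    "protein_group",
    "rt_minutes",
    "ms1_intensity",
    "ms2_intensity",
    "q_value",
)

RECORD_COLUMNS = [
    "run_id",
    "modified_sequence",
    "stripped_sequence",
    "charge",
    "precursor_mz",
    "protein_group",
    "rt_seconds",
    "ms1_intensity",
    "ms2_intensity",
    "q_value",
    "channel_q",
    "translated_q",
    "channel",
    "translated",
]


@dataclass(frozen=True)
class PrecursorRecord:
    """One precursor observation (run x modified sequence x charge)."""

    run_id: str
    modified_sequence: str
    stripped_sequence: str
    charge: int
    protein_group: str
    rt_seconds: float
    q_value: float
    precursor_mz: float = np.nan
    ms1_intensity: float = np.nan
    ms2_intensity: float = np.nan
    channel_q: float = np.nan
    translated_q: float = np.nan
    channel: str = "unlabeled"
    translated: bool = False


@dataclass
class PrecursorTable:
    """Search-report rows as a DataFrame plus the ordered distinct runs."""

    df: pd.DataFrame
    runs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.runs:
            self.runs = list(dict.fromkeys(self.df["run_id"]))

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: list[PrecursorRecord]) -> "PrecursorTable":
        df = pd.DataFrame([r.__dict__ for r in records], columns=RECORD_COLUMNS)
        return cls(df=df)

    def records(self) -> list[PrecursorRecord]:
        return [
            PrecursorRecord(**{k: row[k] for k in RECORD_COLUMNS})
            for _, row in self.df.iterrows()
        ]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return path


_TAG_RE = re.compile(r"\(([^()]*)\)|\[([^\[\]]*)\]")
_MTRAQ_RE = re.compile(r"mTRAQ\D*([048])\b", re.IGNORECASE)


def parse_channel(modified_sequence: str) -> str:
    """plexDIA channel (d0/d4/d8) from the label tags of a modified sequence.

    Accepts the common tag dialects ("mTRAQ-K-0", "mTRAQ-d0", "mTRAQ-n-4",
    ...) anywhere in the sequence; a sequence without an mTRAQ tag is
    ``unlabeled``. Two tags with different mass deltas in one sequence
    are contradictory and raise.
    """
    deltas: set[str] = set()
    for m in _TAG_RE.finditer(modified_sequence):
        tag = m.group(1) or m.group(2) or ""
        hit = _MTRAQ_RE.search(tag)
        if hit:
            deltas.add(hit.group(1))
    if not deltas:
        return "unlabeled"
    if len(deltas) > 1:
        raise AmbiguousChannelError(
            f"conflicting mTRAQ tags {sorted(deltas)} in {modified_sequence!r}"
        )
    return f"d{deltas.pop()}"


def strip_sequence(modified_sequence: str) -> str:
    """Remove all bracketed modification tags, leaving the plain sequence."""
    return _TAG_RE.sub("", modified_sequence)


def read_report(
    path: str | Path,
    q_threshold: float = 0.01,
    gating_column: str = "q_value",
) -> PrecursorTable:
    """Read a DIA-NN-style TSV report into a PrecursorTable.

    Rows whose ``gating_column`` q-value exceeds ``q_threshold`` are
    dropped (pass 1.0 to keep everything, e.g. for FDR curves). The
    plexDIA channel is parsed from the modification tags; the
    ``translated`` flag marks identifications that exist only by
    cross-channel propagation: their translated q-value passes the
    threshold while the direct channel q-value (or the run q-value when
    no channel q-value is reported) does not.

    Duplicate (run, modified sequence, charge) rows keep the lowest
    q-value; collisions are logged.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    resolved: dict[str, str] = {}
    for canon, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in raw.columns:
                resolved[canon] = alias
                break
    missing = [c for c in MANDATORY if c not in resolved]
    if missing:
        raise SchemaError(
            f"report {path} missing mandatory column(s): "
            + ", ".join(COLUMN_ALIASES[c][0] for c in missing)
        )

    df = pd.DataFrame({canon: raw[col] for canon, col in resolved.items()})
    for col in ("q_value", "channel_q", "translated_q", "ms1_intensity",
                "ms2_intensity", "rt_minutes", "precursor_mz"):
        if col in df.columns:
            df[col] = _numeric(df[col], col, path)
        else:
            df[col] = np.nan
    df["charge"] = _numeric(df["charge"], "charge", path).astype(int)
    if "stripped_sequence" not in df.columns:
        df["stripped_sequence"] = df["modified_sequence"].map(strip_sequence)
    df["rt_seconds"] = df.pop("rt_minutes") * 60.0
    df["channel"] = df["modified_sequence"].map(parse_channel)

    direct_q = df["channel_q"].where(df["channel_q"].notna(), df["q_value"])
    df["translated"] = (
        df["translated_q"].notna()
        & (df["translated_q"] <= q_threshold)
        & (direct_q > q_threshold)
    )

    gate = df[gating_column].where(df[gating_column].notna(), df["q_value"])
    df = df[gate <= q_threshold].copy()

    dup = df.duplicated(["run_id", "modified_sequence", "charge"], keep=False)
    if dup.any():
        log.warning(
            "%d duplicate (run, precursor) rows; keeping lowest q-value",
            int(dup.sum()),
        )
        df = (
            df.sort_values("q_value", kind="stable")
            .drop_duplicates(["run_id", "modified_sequence", "charge"])
            .sort_index()
        )
    df = df[RECORD_COLUMNS].reset_index(drop=True)
    return PrecursorTable(df=df)


def _numeric(series: pd.Series, name: str, path: Path) -> pd.Series:
    s = series.replace("", np.nan)
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna() & s.notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"report {path}: non-numeric value {s.iloc[row]!r} in column "
            f"'{name}' at data row {row}"
        )
    return out
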