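"""Readers and writers for the delimited-text interchange formats.

Everything the pipeline consumes or emits is comma-separated UTF-8 text
with a header row: sample logs (one row per chamber per sampled time
point), colony metadata, and rate tables.  Written tables carry a
``# key: value`` provenance preamble including the config hash, so a
result file is traceable to the exact settings that produced it.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "read_sample_log",
    "read_colony_metadata",
    "write_rates",
    "read_rates",
]

_SAMPLE_REQUIRED = ["chamber_id", "role", "phase", "TA", "O2", "salinity", "temperature"]
_SAMPLE_NUMERIC = ["TA", "O2", "salinity", "temperature", "time_h",
                   "extracted_volume_ml", "residual_volume_ml"]
_COLONY_REQUIRED = ["chamber_id", "colony_id", "species", "site", "surface_area_m2"]


def _clock_to_hours(series: pd.Series, origin: Optional[pd.Timestamp] = None) -> pd.Series:
    """Convert ISO-8601 clock times to fractional hours since the first sample."""
    ts = pd.to_datetime(series, format="ISO8601")
    if origin is None:
        origin = ts.min()
    return (ts - origin).dt.total_seconds() / 3600.0


def read_sample_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a chamber sample log.

    Required columns: chamber_id, role, phase, TA, O2, salinity,
    temperature, and either ``time_h`` (fractional hours) or ``time``
    (ISO-8601 clock time, converted per day at ingest).  Optional: day,
    cycle, site, extracted_volume_ml, residual_volume_ml, pH.  Bad rows
    are reported with their line numbers; duplicate
    (chamber, day, cycle, phase, time) keys are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty sample log")
        return df
    missing = [c for c in _SAMPLE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    if "time_h" not in df.columns:
        if "time" not in df.columns:
            raise ValueError(f"{path}: needs a 'time_h' or 'time' column")
        if "day" in df.columns:
            df["time_h"] = (
                df.groupby("day")["time"].transform(_clock_to_hours)
            )
        else:
            df["time_h"] = _clock_to_hours(df["time"])

    bad_lines = []
    for col in _SAMPLE_NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for idx in df.index[bad]:
            bad_lines.append(f"line {idx + 2}: non-numeric {col}={df.at[idx, col]!r}")
        df[col] = coerced
    for col, allowed in (("role", {"treatment", "control"}),
                         ("phase", {"light", "dark"})):
        bad = ~df[col].isin(allowed)
        for idx in df.index[bad]:
            bad_lines.append(f"line {idx + 2}: invalid {col}={df.at[idx, col]!r}")
    if bad_lines:
        raise ValueError(f"{path}: invalid rows:\n  " + "\n  ".join(bad_lines))

    keys = ["chamber_id", "phase", "time_h"]
    for extra in ("day", "cycle"):
        if extra in df.columns:
            keys.append(extra)
    dup = df.duplicated(subset=keys)
    if dup.any():
        lines = [str(i + 2) for i in df.index[dup]]
        raise ValueError(
            f"{path}: duplicate (chamber, phase, time) rows at line(s) {', '.join(lines)}"
        )
    return df


def read_colony_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the colony metadata table."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty colony metadata")
        return df
    missing = [c for c in _COLONY_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    df["surface_area_m2"] = pd.to_numeric(df["surface_area_m2"])
    if (df["surface_area_m2"] <= 0).any():
        bad = df.index[df["surface_area_m2"] <= 0] + 2
        raise ValueError(f"{path}: non-positive surface area at line(s) {list(bad)}")
    if df["chamber_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate chamber_id entries")
    return df


def write_rates(path: str | Path, rates: pd.DataFrame, provenance: dict) -> None:
    """Write a rates table with a commented provenance preamble."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key in sorted(provenance):
            fh.write(f"# {key}: {provenance[key]}\n")
        rates.to_csv(fh, index=False)


def read_rates(path: str | Path):
    """Read a rates table written by :func:`write_rates`; returns (table, provenance)."""
    path = Path(path)
    provenance = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                provenance[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    return df, provenance
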