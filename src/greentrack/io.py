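"""Reading and writing the pipeline's tabular inputs and outputs.

Raw fixes arrive as CSV with columns ``device_id,timestamp,lon,lat,alt``
(ISO-8601 timestamps); home locations as ``device_id,lon,lat``.  Internally
a fix frame carries ``device_id`` (str), ``t`` (epoch seconds, float),
``lon``, ``lat``, ``alt`` and -- after projection -- ``x``, ``y`` in metres.
Malformed rows are dropped and counted, never fatal; an input with zero
parseable rows is an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError

FIX_COLUMNS = ["device_id", "timestamp", "lon", "lat", "alt"]


@dataclass
class ParseReport:
    """Counts of rows excluded while parsing a fix file."""

    n_rows: int = 0
    n_malformed: int = 0
    n_duplicates: int = 0
    messages: list[str] = field(default_factory=list)


def read_fixes(path: str | Path, tz: str = "UTC") -> tuple[pd.DataFrame, ParseReport]:
    """Parse a raw fix CSV into a time-sorted fix frame.

    Rows with unparseable timestamps or non-numeric coordinates are excluded
    and counted in the returned :class:`ParseReport`.  Duplicate
    (device, timestamp) pairs keep the first occurrence.  Naive timestamps
    are interpreted in ``tz``.

    Raises
    ------
    FormatError
        if a required column is missing.
    EmptyInputError
        if no row parses.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in FIX_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"fix file {path} is missing required column(s): {', '.join(missing)}")
    report = ParseReport(n_rows=len(raw))

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", utc=False, format="ISO8601")
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(tz)
    else:
        ts = ts.dt.tz_convert(tz)
    nums = {c: pd.to_numeric(raw[c], errors="coerce") for c in ("lon", "lat", "alt")}
    ok = ts.notna() & raw["device_id"].notna()
    for c in ("lon", "lat"):
        ok &= nums[c].notna()
    report.n_malformed = int((~ok).sum())
    if report.n_malformed:
        report.messages.append(f"{report.n_malformed} malformed row(s) excluded")
        warnings.warn(report.messages[-1], stacklevel=2)
    if not ok.any():
        raise EmptyInputError(f"no parseable rows in {path}")

    frame = pd.DataFrame(
        {
            "device_id": raw.loc[ok, "device_id"].astype(str).to_numpy(),
            "t": (ts[ok].astype("int64") / 1e9).to_numpy(),
            "lon": nums["lon"][ok].to_numpy(),
            "lat": nums["lat"][ok].to_numpy(),
            "alt": nums["alt"][ok].to_numpy(),
        }
    )
    if "trip_id" in raw.columns:  # round-tripping a segmented file
        frame["trip_id"] = raw.loc[ok, "trip_id"].to_numpy()
    frame = frame.sort_values(["device_id", "t"], kind="stable")
    dup = frame.duplicated(["device_id", "t"], keep="first")
    report.n_duplicates = int(dup.sum())
    if report.n_duplicates:
        report.messages.append(
            f"{report.n_duplicates} duplicate (device, timestamp) row(s) dropped"
        )
        warnings.warn(report.messages[-1], stacklevel=2)
    return frame[~dup].reset_index(drop=True), report


def write_fixes(frame: pd.DataFrame, path: str | Path, tz: str = "UTC") -> None:
    """Serialise a fix frame back to the input CSV dialect."""
    out = pd.DataFrame(
        {
            "device_id": frame["device_id"],
            "timestamp": pd.to_datetime(frame["t"], unit="s", utc=True)
            .dt.tz_convert(tz)
            .dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
            "lon": frame["lon"],
            "lat": frame["lat"],
            "alt": frame["alt"],
        }
    )
    for extra in ("trip_id",):
        if extra in frame.columns:
            out[extra] = frame[extra].to_numpy()
    out.to_csv(path, index=False)


def read_homes(path: str | Path) -> pd.DataFrame:
    """Parse home locations (``device_id,lon,lat``; at most one per device)."""
    raw = pd.read_csv(path, dtype={"device_id": str})
    missing = [c for c in ("device_id", "lon", "lat") if c not in raw.columns]
    if missing:
        raise FormatError(f"home file {path} is missing column(s): {', '.join(missing)}")
    if raw["device_id"].duplicated().any():
        dups = raw.loc[raw["device_id"].duplicated(), "device_id"].unique().tolist()
        raise FormatError(f"multiple home locations for device(s): {dups}")
    return raw[["device_id", "lon", "lat"]].copy()


def trips_to_frame(trips: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-trip frames into one frame (empty-safe)."""
    if not trips:
        return pd.DataFrame(
            {c: pd.Series(dtype=f) for c, f in
             [("device_id", str), ("trip_id", object), ("t", float),
              ("x", float), ("y", float), ("alt", float)]}
        )
    return pd.concat(trips, ignore_index=True)


def iter_trips(frame: pd.DataFrame, by=("device_id", "trip_id")):
    """Yield per-trip sub-frames in (device, trip) order."""
    if frame.empty:
        return
    for _, g in frame.groupby(list(by), sort=True):
        yield g.reset_index(drop=True)


def ensure_float_frame(frame: pd.DataFrame, cols: tuple[str, ...]) -> None:
    for c in cols:
        frame[c] = np.asarray(frame[c], dtype=float)
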