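"""Stage 1: split each device's fix stream into candidate trips at time gaps.

Geofence-triggered recording emits fixes only near greenspace, so a device's
stream is naturally punctuated by silences between visits.  A gap strictly
greater than ``gap_s`` (default 600 s) between consecutive fixes starts a new
trip; a gap exactly equal to the threshold does not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def split_trips(track: pd.DataFrame, gap_s: float) -> list[pd.DataFrame]:
    """Partition one device's time-sorted fixes into trips.

    Returns per-trip frames carrying a dense ``trip_id`` ordinal (0-based,
    ordered by start time).  Concatenating the outputs reproduces the input
    fixes exactly; a break occurs iff dt > gap_s.
    """
    if gap_s <= 0:
        raise ValueError("gap_s must be positive")
    if track.empty:
        return []
    t = track["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("track is not time-sorted")
    breaks = np.flatnonzero(np.diff(t) > gap_s) + 1
    trips = []
    for tid, chunk in enumerate(np.split(np.arange(len(track)), breaks)):
        g = track.iloc[chunk].copy()
        g["trip_id"] = tid
        trips.append(g.reset_index(drop=True))
    return trips


def segment_frame(frame: pd.DataFrame, gap_s: float) -> pd.DataFrame:
    """Apply :func:`split_trips` per device and return one frame with trip_id."""
    if frame.empty:
        out = frame.copy()
        out["trip_id"] = pd.Series(dtype=int)
        return out
    parts = []
    for _, track in frame.groupby("device_id", sort=True):
        parts.extend(split_trips(track.reset_index(drop=True), gap_s))
    return pd.concat(parts, ignore_index=True)
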