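"""Stage 2: data cleaning.

Three filters applied per trip, in order:

1. altitude -- drop individual fixes whose reported altitude falls outside
   the plausible band for the study area plus error buffers ([18, 622] m at
   defaults; satellite-error fixes often report ~0 m or wildly high values);
2. too-short -- drop trips spanning < 70 s or holding < 3 fixes (more likely
   a pass-by within the geofence than a visit);
3. speed jumps -- the iterative quality-segment procedure: split the trip at
   consecutive-pair displacements exceeding ``vmax_clean_ms * dt +
   jump_allowance_m`` (7 m/s + 20 m at defaults, 3-D distance), repeatedly
   remove the shorter of the first pair of adjacent segments, re-segment,
   until no violation remains.  This removes GPS jump artefacts and most
   vehicular travel along greenspace edges.

After speed cleaning the duration/point-count check is applied again.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .projection import require_projected, step_lengths_3d


def filter_altitude(trip: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Drop fixes with altitude outside [alt_lo, alt_hi]; NaN altitude is kept.

    Only individual fixes are removed, never whole trips; a trip may come
    back empty.
    """
    alt = trip["alt"].to_numpy(dtype=float)
    keep = ((alt >= cfg.alt_lo) & (alt <= cfg.alt_hi)) | ~np.isfinite(alt)
    return trip[keep].reset_index(drop=True)


def is_too_short(trip: pd.DataFrame, cfg: PipelineConfig) -> bool:
    """True iff the trip spans < min_trip_duration_s or has < min_trip_points."""
    if len(trip) < cfg.min_trip_points:
        return True
    t = trip["t"].to_numpy(dtype=float)
    return bool(t[-1] - t[0] < cfg.min_trip_duration_s)


def _violations(trip: pd.DataFrame, cfg: PipelineConfig) -> np.ndarray:
    """Boolean per consecutive pair: displacement exceeds the jump criterion."""
    d = step_lengths_3d(trip)
    dt = np.diff(trip["t"].to_numpy(dtype=float))
    return d > cfg.vmax_clean_ms * dt + cfg.jump_allowance_m


def quality_segments(trip: pd.DataFrame, cfg: PipelineConfig) -> list[tuple[int, int]]:
    """Inclusive (start, end) index ranges of maximal jump-free runs."""
    n = len(trip)
    if n == 0:
        return []
    viol = _violations(trip, cfg)
    bounds = np.flatnonzero(viol) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds - 1, [n - 1]))
    return list(zip(starts.tolist(), ends.tolist()))


def enforce_speed_limit(trip: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Iteratively remove the shorter of adjacent quality segments.

    Left-to-right: the first adjacent pair is compared, the segment with
    fewer fixes removed (tie: the later one), and the trip re-segmented;
    repeated until a single quality segment remains.  The result is a
    subsequence of the input fixes with every pair within the jump limit.
    """
    require_projected(trip)
    cur = trip.reset_index(drop=True)
    while True:
        segs = quality_segments(cur, cfg)
        if len(segs) <= 1:
            return cur
        (s0, e0), (s1, e1) = segs[0], segs[1]
        n0, n1 = e0 - s0 + 1, e1 - s1 + 1
        lo, hi = (s0, e0) if n0 < n1 else (s1, e1)
        keep = np.ones(len(cur), dtype=bool)
        keep[lo : hi + 1] = False
        cur = cur[keep].reset_index(drop=True)


def clean(
    trips: list[pd.DataFrame], cfg: PipelineConfig
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Run the full stage-2 composition over a batch of trips.

    Returns the surviving trips and an audit frame with one row per
    (trip, sub-stage) recording fixes removed or the removal reason.
    """
    out: list[pd.DataFrame] = []
    audit: list[dict] = []

    def note(trip, stage, fixes_removed, reason=""):
        audit.append(
            {
                "device_id": trip["device_id"].iloc[0] if len(trip) else "",
                "trip_id": trip["trip_id"].iloc[0] if len(trip) else "",
                "stage": stage,
                "fixes_removed": fixes_removed,
                "reason": reason,
            }
        )

    for trip in trips:
        n0 = len(trip)
        t1 = filter_altitude(trip, cfg)
        if len(t1) < n0:
            note(trip, "altitude", n0 - len(t1), "altitude outside plausible band")
        if len(t1) == 0 or is_too_short(t1, cfg):
            note(trip, "too_short", len(t1), "short trip (pre-speed)")
            continue
        t2 = enforce_speed_limit(t1, cfg)
        if len(t2) < len(t1):
            note(trip, "speed", len(t1) - len(t2), "jump/quality-segment removal")
        if is_too_short(t2, cfg):
            note(trip, "too_short_final", len(t2), "short trip (post-speed)")
            continue
        out.append(t2)
    audit_frame = pd.DataFrame(
        audit, columns=["device_id", "trip_id", "stage", "fixes_removed", "reason"]
    )
    return out, audit_frame
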