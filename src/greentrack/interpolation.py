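"""Stage 3: resample each cleaned trip to a time-regular vertex sequence.

Fix density varies with signal quality and with fixes removed during
cleaning; downstream window filters and time-based attributes want vertices
at (approximately) equal time intervals.  Linear interpolation along the fix
polyline places a vertex every ``interp_interval_s`` seconds from the trip
start, plus the final fix when it is off the grid; no extrapolation, no
smoothing (smoothing bends outside paths across greenspace boundaries).

Altitude is not interpolated: stages 4-5 use planar geometry only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import StateError
from .projection import require_projected

VERTEX_COLUMNS = ["device_id", "trip_id", "t", "x", "y"]


def interpolate(trip: pd.DataFrame, interval_s: float = 10.0) -> pd.DataFrame:
    """Build the interpolated path of one cleaned trip.

    Vertex times are ``t0 + k*interval_s`` for k = 0..floor(T/interval_s),
    with the final fix time appended when T is not a multiple of the
    interval, so the first and last vertices coincide with the first and
    last source fixes.
    """
    require_projected(trip)
    t = trip["t"].to_numpy(dtype=float)
    if len(t) == 0:
        raise StateError("cannot interpolate an empty trip")
    if np.any(np.diff(t) < 0):
        raise StateError("trip is not time-sorted")
    t0, t1 = t[0], t[-1]
    span = t1 - t0
    grid = t0 + interval_s * np.arange(int(np.floor(span / interval_s + 1e-9)) + 1)
    if grid[-1] < t1 - 1e-9:
        grid = np.append(grid, t1)
    x = np.interp(grid, t, trip["x"].to_numpy(dtype=float))
    y = np.interp(grid, t, trip["y"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "device_id": trip["device_id"].iloc[0],
            "trip_id": trip["trip_id"].iloc[0],
            "t": grid,
            "x": x,
            "y": y,
        }
    )


def interpolate_trips(trips: list[pd.DataFrame], interval_s: float = 10.0) -> list[pd.DataFrame]:
    return [interpolate(t, interval_s) for t in trips]


def path_length(path: pd.DataFrame) -> float:
    """Planar polyline length of a vertex sequence, metres."""
    return float(
        np.hypot(
            np.diff(path["x"].to_numpy(dtype=float)),
            np.diff(path["y"].to_numpy(dtype=float)),
        ).sum()
    )
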