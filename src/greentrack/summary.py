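"""Trip-level and user-averaged summaries of processed greenspace visits.

Two weightings are reported: per-trip statistics (each trip counts once)
and user-averaged statistics (characteristics first averaged within each
device, so every user contributes equally regardless of how many trips they
recorded).  Per-user visit frequency is trips per day over the user's
recording period (first to last trip start date, inclusive, minimum one
day), and daily/weekly totals extrapolate frequency x mean duration (or
distance).  Trip destinations are tallied by greenspace type, counting each
distinct type a trip touches once.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .gsmap import GreenspaceMap

#: characteristics summarised, in reporting order
CHARACTERISTICS = (
    "duration_min",
    "length_m",
    "length_in_greenspace_m",
    "avg_speed_ms",
    "home_dist_m",
)


def _with_duration_min(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["duration_min"] = out["duration_s"] / 60.0
    return out


def summarise_trips(
    records: pd.DataFrame, max_flags: int = 5, label: str = ""
) -> pd.DataFrame:
    """Mean/median/SD of trip characteristics over trips with <= max_flags.

    Each trip is weighted equally.  Returns one row per characteristic with
    the selection count in every row; an empty selection yields NaN
    statistics and count 0.
    """
    sel = _with_duration_min(records)
    if "n_flags" in sel.columns:
        sel = sel[sel["n_flags"] <= max_flags]
    rows = []
    for ch in CHARACTERISTICS:
        v = sel[ch].dropna() if ch in sel.columns else pd.Series(dtype=float)
        rows.append(
            {
                "group": label,
                "characteristic": ch,
                "mean": v.mean() if len(v) else np.nan,
                "median": v.median() if len(v) else np.nan,
                "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                "count": len(sel),
            }
        )
    return pd.DataFrame(rows)


def visit_frequency(records: pd.DataFrame, device_id: str) -> float:
    """Trips per day over the device's recording period.

    The period runs from the date of the first trip start to the date of
    the last, inclusive in whole days (a single trip gives 1 trip/day).
    """
    mine = records[records["device_id"] == device_id]
    if mine.empty:
        raise KeyError(f"no trips for device {device_id!r}")
    days = pd.to_datetime(mine["t_start"], unit="s", utc=True).dt.normalize()
    period_days = (days.max() - days.min()).days + 1
    return len(mine) / period_days


def user_average(records: pd.DataFrame) -> pd.DataFrame:
    """Per-device averages of trip characteristics plus visit frequency.

    One row per device carrying n_trips, the mean/median/sd of each
    characteristic over that user's trips, and frequency_per_day.
    Summarising this frame weights users equally.
    """
    recs = _with_duration_min(records)
    rows = []
    for device, g in recs.groupby("device_id", sort=True):
        row: dict = {"device_id": device, "n_trips": len(g)}
        for ch in CHARACTERISTICS:
            v = g[ch].dropna()
            row[f"mean_{ch}"] = v.mean() if len(v) else np.nan
            row[f"median_{ch}"] = v.median() if len(v) else np.nan
            row[f"sd_{ch}"] = v.std(ddof=1) if len(v) > 1 else np.nan
        row["frequency_per_day"] = visit_frequency(records, device)
        rows.append(row)
    return pd.DataFrame(rows)


def extrapolate(users: pd.DataFrame) -> pd.DataFrame:
    """Fill daily and weekly duration/distance totals per user.

    daily = frequency_per_day x mean per-trip value; weekly = 7 x daily.
    """
    out = users.copy()
    out["daily_duration_min"] = out["frequency_per_day"] * out["mean_duration_min"]
    out["weekly_duration_min"] = 7.0 * out["daily_duration_min"]
    out["daily_distance_m"] = out["frequency_per_day"] * out["mean_length_m"]
    out["weekly_distance_m"] = 7.0 * out["daily_distance_m"]
    return out


def extrapolate_totals(
    frequency_per_day: float, mean_duration_min: float, mean_distance_m: float
) -> dict[str, float]:
    """Scalar daily/weekly totals from summary means (worked-example helper)."""
    daily_dur = frequency_per_day * mean_duration_min
    daily_dist = frequency_per_day * mean_distance_m
    return {
        "daily_duration_min": daily_dur,
        "weekly_duration_min": 7.0 * daily_dur,
        "daily_distance_m": daily_dist,
        "weekly_distance_m": 7.0 * daily_dist,
    }


def destination_type_counts(
    records: pd.DataFrame, gsmap: GreenspaceMap, per_user: bool = False
) -> dict[str, int]:
    """Trips (or users) per greenspace type.

    Per-trip (default): every distinct type a trip touches is incremented
    once, so column sums can exceed the trip count.  Per-user: each user
    counts once per distinct greenspace they visited, whatever the number
    of visits; the greenspace's type is incremented per such (user, space)
    pair.
    """
    counts: Counter[str] = Counter({t: 0 for t in gsmap.typology})
    if per_user:
        for _, g in records.groupby("device_id"):
            visited: set[str] = set()
            for ids in g["greenspace_ids_visited"]:
                visited.update(ids)
            for gid in visited:
                counts[gsmap.type_of(gid)] += 1
    else:
        for types in records["greenspace_types_visited"]:
            for t in set(types):
                counts[t] += 1
    return dict(counts)


def plot_characteristics(records: pd.DataFrame, bins: int = 30):
    """Histograms of the five trip characteristics (one axes each)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    recs = _with_duration_min(records)
    fig, axes = plt.subplots(1, len(CHARACTERISTICS), figsize=(4 * len(CHARACTERISTICS), 3))
    for ax, ch in zip(np.atleast_1d(axes), CHARACTERISTICS):
        v = recs[ch].dropna()
        if len(v):
            ax.hist(v, bins=bins)
        ax.set_xlabel(ch)
    fig.tight_layout()
    return fig
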