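"""Stage 5: per-trip attributes and the five certainty flags.

Attributes are computed on the annotated interpolated path: polyline length
and duration, the length and share of the trip inside greenspace and inside
buildings (distance attributed per segment by its midpoint's membership;
time per vertex, each vertex weighted by half its adjacent intervals),
nearest-entrance distances of the interpolated start and end points, average
speed, and distance from the user's home to the trip start.

Each flag records *failure* of one validity criterion -- zero flags means
highest confidence that the trip is a genuine, complete, non-vehicular
greenspace visit:

=================== ===========================================================
short_distance      trip length <= 25 m (GPS not updating, or no real trip)
entrance_far        start or end > 25 m from the nearest mapped entrance
                    (likely incomplete data)
high_speed          average speed >= 5 m/s (probably vehicular)
in_buildings        > 50 % of time or of distance inside buildings
outside_greenspace  < 50 % of time or of distance inside greenspace
=================== ===========================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .gsmap import GreenspaceMap
from .stage4 import require_annotated

FLAG_NAMES = (
    "short_distance",
    "entrance_far",
    "high_speed",
    "in_buildings",
    "outside_greenspace",
)


@dataclass(frozen=True)
class TripAttributes:
    duration_s: float
    length_m: float
    length_in_greenspace_m: float
    pct_time_in_greenspace: float
    pct_dist_in_greenspace: float
    n_unique_greenspaces: int
    start_entrance_dist_m: float
    end_entrance_dist_m: float
    pct_time_in_buildings: float
    pct_dist_in_buildings: float
    avg_speed_ms: float
    home_dist_m: float | None = None


@dataclass(frozen=True)
class TripFlags:
    short_distance: bool
    entrance_far: bool
    high_speed: bool
    in_buildings: bool
    outside_greenspace: bool

    @property
    def n_flags(self) -> int:
        return sum(
            (self.short_distance, self.entrance_far, self.high_speed,
             self.in_buildings, self.outside_greenspace)
        )


def _time_weights(t: np.ndarray) -> np.ndarray:
    """Half-interval vertex weights; they sum to the trip duration."""
    w = np.zeros_like(t)
    dt = np.diff(t)
    w[:-1] += dt / 2.0
    w[1:] += dt / 2.0
    return w


def compute_attributes(
    path: pd.DataFrame,
    gsmap: GreenspaceMap,
    home: tuple[float, float] | None = None,
) -> TripAttributes:
    """Compute the stage-5 attribute set for one annotated path.

    ``home`` is the user's home point in metric coordinates, or None (then
    ``home_dist_m`` is None).  With no mapped entrances the entrance
    distances are +inf (and will raise the incomplete-data flag).
    """
    require_annotated(path)
    if len(path) < 2:
        raise ValueError("attributes require a path of at least 2 vertices")
    t = path["t"].to_numpy(dtype=float)
    x = path["x"].to_numpy(dtype=float)
    y = path["y"].to_numpy(dtype=float)
    inside = path["inside_greenspace"].to_numpy(dtype=bool)
    in_bld = path["inside_building"].to_numpy(dtype=bool)

    duration = float(t[-1] - t[0])
    seg_len = np.hypot(np.diff(x), np.diff(y))
    length = float(seg_len.sum())

    # distance attribution: a segment is inside iff its midpoint is
    mx, my = (x[:-1] + x[1:]) / 2.0, (y[:-1] + y[1:]) / 2.0
    mid_inside, _ = gsmap.greenspace_membership(mx, my)
    mid_bld = gsmap.building_membership(mx, my)
    len_gs = float(seg_len[mid_inside].sum())
    len_bld = float(seg_len[mid_bld].sum())
    if length > 0:
        pct_dist_gs = len_gs / length
        pct_dist_bld = len_bld / length
    else:  # degenerate zero-length path: fall back to vertex membership
        pct_dist_gs = 1.0 if inside[0] else 0.0
        pct_dist_bld = 1.0 if in_bld[0] else 0.0

    w = _time_weights(t)
    pct_time_gs = float(w[inside].sum() / duration) if duration > 0 else float(inside[0])
    pct_time_bld = float(w[in_bld].sum() / duration) if duration > 0 else float(in_bld[0])

    visited: set[str] = set()
    for ids in path["greenspace_ids"]:
        visited.update(ids)

    home_dist = None
    if home is not None:
        home_dist = float(math.hypot(x[0] - home[0], y[0] - home[1]))

    return TripAttributes(
        duration_s=duration,
        length_m=length,
        length_in_greenspace_m=len_gs,
        pct_time_in_greenspace=pct_time_gs,
        pct_dist_in_greenspace=pct_dist_gs,
        n_unique_greenspaces=len(visited),
        start_entrance_dist_m=gsmap.nearest_entrance_distance(x[0], y[0]),
        end_entrance_dist_m=gsmap.nearest_entrance_distance(x[-1], y[-1]),
        pct_time_in_buildings=pct_time_bld,
        pct_dist_in_buildings=pct_dist_bld,
        avg_speed_ms=length / duration if duration > 0 else float("nan"),
        home_dist_m=home_dist,
    )


def assign_flags(attrs: TripAttributes, cfg: PipelineConfig) -> TripFlags:
    """Evaluate the five certainty criteria; a raised flag marks a failure.

    Boundary conventions follow the criteria literally: a 25 m trip is
    short (distance must *exceed* 25 m); exactly 5 m/s is fast (speed must
    be *below* 5 m/s); exactly 50 % of time/distance inside greenspace or
    outside buildings passes.
    """
    return TripFlags(
        short_distance=attrs.length_m <= cfg.flag_min_distance_m,
        entrance_far=(
            attrs.start_entrance_dist_m > cfg.flag_entrance_max_m
            or attrs.end_entrance_dist_m > cfg.flag_entrance_max_m
        ),
        high_speed=attrs.avg_speed_ms >= cfg.flag_vmax_ms,
        in_buildings=(
            attrs.pct_time_in_buildings > cfg.flag_building_max_frac
            or attrs.pct_dist_in_buildings > cfg.flag_building_max_frac
        ),
        outside_greenspace=(
            attrs.pct_time_in_greenspace < cfg.flag_inside_min_frac
            or attrs.pct_dist_in_greenspace < cfg.flag_inside_min_frac
        ),
    )


def build_records(
    paths: list[pd.DataFrame],
    gsmap: GreenspaceMap,
    cfg: PipelineConfig,
    homes: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """One row per surviving path: attributes, flags, n_flags, types visited."""
    homes = homes or {}
    rows = []
    for path in paths:
        device = path["device_id"].iloc[0]
        attrs = compute_attributes(path, gsmap, home=homes.get(device))
        flags = assign_flags(attrs, cfg)
        visited: set[str] = set()
        for ids in path["greenspace_ids"]:
            visited.update(ids)
        types = tuple(sorted({gsmap.type_of(g) for g in visited}))
        row = {
            "device_id": device,
            "trip_id": str(path["trip_id"].iloc[0]),
            "t_start": float(path["t"].iloc[0]),
            **{k: getattr(attrs, k) for k in TripAttributes.__dataclass_fields__},
            **{f"flag_{name}": getattr(flags, name) for name in FLAG_NAMES},
            "n_flags": flags.n_flags,
            "greenspace_ids_visited": tuple(sorted(visited)),
            "greenspace_types_visited": types,
        }
        row["home_dist_m"] = attrs.home_dist_m if attrs.home_dist_m is not None else np.nan
        rows.append(row)
    columns = (
        ["device_id", "trip_id", "t_start"]
        + list(TripAttributes.__dataclass_fields__)
        + [f"flag_{n}" for n in FLAG_NAMES]
        + ["n_flags", "greenspace_ids_visited", "greenspace_types_visited"]
    )
    return pd.DataFrame(rows, columns=columns)
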