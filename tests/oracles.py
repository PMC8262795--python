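"""Independent reference implementations used to check the pipeline.

Everything here is deliberately written the slow, literal way (plain Python
loops, per-pair recomputation) and shares no code with the package beyond
the data containers.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def haversine_m(lon1, lat1, lon2, lat2, radius=6371008.8):
    """Great-circle distance on the sphere, metres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


def brute_force_speed_clean(trip: pd.DataFrame, vmax: float, allowance: float) -> pd.DataFrame:
    """Literal simulation of the pairwise shorter-quality-segment removal loop.

    Split at every consecutive pair whose 3-D displacement exceeds
    vmax*dt + allowance; while more than one segment remains, compare the
    first adjacent pair, delete the one with fewer fixes (tie: the later),
    rebuild the fix list and re-split from scratch.
    """
    rows = list(trip.itertuples(index=False))

    def violates(a, b):
        dz = (a.alt - b.alt) if (math.isfinite(a.alt) and math.isfinite(b.alt)) else 0.0
        d = math.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + dz**2)
        return d > vmax * (b.t - a.t) + allowance

    def segments(seq):
        segs, cur = [], [seq[0]] if seq else []
        for prev, nxt in zip(seq, seq[1:]):
            if violates(prev, nxt):
                segs.append(cur)
                cur = [nxt]
            else:
                cur.append(nxt)
        if cur:
            segs.append(cur)
        return segs

    while rows:
        segs = segments(rows)
        if len(segs) <= 1:
            break
        first, second = segs[0], segs[1]
        doomed = first if len(first) < len(second) else second
        doomed_ids = {id(r) for r in doomed}
        rows = [r for r in rows if id(r) not in doomed_ids]
    return pd.DataFrame(rows, columns=trip.columns).reset_index(drop=True)


def window_means_brute(t: np.ndarray, values: np.ndarray, half: float) -> np.ndarray:
    """Centred time-window means by explicit per-vertex scan."""
    out = np.empty(len(t))
    for i, ti in enumerate(t):
        sel = [v for tj, v in zip(t, values) if abs(tj - ti) <= half]
        out[i] = sum(sel) / len(sel)
    return out


def flag_predicate_table(attrs, cfg) -> dict[str, bool]:
    """Independently coded certainty-flag truth table."""
    return {
        "short_distance": not (attrs.length_m > cfg.flag_min_distance_m),
        "entrance_far": not (
            attrs.start_entrance_dist_m <= cfg.flag_entrance_max_m
            and attrs.end_entrance_dist_m <= cfg.flag_entrance_max_m
        ),
        "high_speed": not (attrs.avg_speed_ms < cfg.flag_vmax_ms),
        "in_buildings": not (
            attrs.pct_time_in_buildings <= cfg.flag_building_max_frac
            and attrs.pct_dist_in_buildings <= cfg.flag_building_max_frac
        ),
        "outside_greenspace": not (
            attrs.pct_time_in_greenspace >= cfg.flag_inside_min_frac
            and attrs.pct_dist_in_greenspace >= cfg.flag_inside_min_frac
        ),
    }


def point_in_ring_even_odd(px, py, ring, on_boundary_true=True):
    """Even-odd ray casting with an explicit closed-boundary convention."""
    n = len(ring)
    inside = False
    for i in range(n - 1):
        (x1, y1), (x2, y2) = ring[i], ring[i + 1]
        # boundary check: point on segment
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        if abs(cross) < 1e-9:
            if min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 and \
               min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9:
                return on_boundary_true
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside
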