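"""Stage 4: detect and discard periods spent outside greenspace or too fast.

Because recording is geofence-triggered (fixes within ~10 m of boundaries),
many apparent trips are people or vehicles travelling along the *outside*
of a greenspace.  Each interpolated vertex is annotated by point-in-polygon
against the map; a centred moving average over ~5 minutes of travel is then
taken of (a) the proportion of vertices inside greenspace and (b) vertex
speed.  Vertices whose window average is below 50 % inside, or above 7 m/s,
are discarded; surviving runs become separate paths (trip splitting), and
path ends are trimmed to at most one vertex outside boundaries.

Paths shorter than the window use a single whole-path proportion and mean
speed instead, and are kept or discarded as a whole.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import CRSError, StateError
from .gsmap import GreenspaceMap

ANNOTATION_COLUMNS = ("inside_greenspace", "inside_building", "greenspace_ids")


def annotate(path: pd.DataFrame, gsmap: GreenspaceMap, crs=None) -> pd.DataFrame:
    """Set per-vertex greenspace/building membership by point-in-polygon.

    Polygon boundaries count as inside.  ``greenspace_ids`` holds the tuple
    of ids of all greenspaces containing the vertex.
    """
    if crs is not None and gsmap.crs is not None and crs != gsmap.crs:
        raise CRSError("path and map are in different coordinate systems")
    out = path.copy()
    x = out["x"].to_numpy(dtype=float)
    y = out["y"].to_numpy(dtype=float)
    inside, ids = gsmap.greenspace_membership(x, y)
    out["inside_greenspace"] = inside
    out["inside_building"] = gsmap.building_membership(x, y)
    out["greenspace_ids"] = ids
    return out


def require_annotated(path: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in path.columns]
    if missing:
        raise StateError(f"path is not annotated (missing {missing}); run annotate() first")


def vertex_speeds(path: pd.DataFrame) -> np.ndarray:
    """Planar speed per vertex; the last vertex inherits the previous speed."""
    t = path["t"].to_numpy(dtype=float)
    if len(t) < 2:
        return np.array([], dtype=float)
    d = np.hypot(
        np.diff(path["x"].to_numpy(dtype=float)),
        np.diff(path["y"].to_numpy(dtype=float)),
    )
    v = d / np.diff(t)
    return np.append(v, v[-1])


def _window_means(t: np.ndarray, values: np.ndarray, half_window: float) -> np.ndarray:
    """Centred time-window means via prefix sums (|t - t_i| <= half_window)."""
    lo = np.searchsorted(t, t - half_window, side="left")
    hi = np.searchsorted(t, t + half_window, side="right")
    csum = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def moving_average_filter(path: pd.DataFrame, cfg: PipelineConfig) -> list[pd.DataFrame]:
    """Discard vertices failing the windowed inside/speed tests; split runs.

    For paths lasting >= ``ma_window_s`` both tests are evaluated per vertex
    on centred windows (truncated at the ends) over the annotated path, the
    discard sets combined, and each maximal surviving run (>= 2 vertices)
    returned as its own path.  Shorter paths are judged whole: kept iff the
    overall inside proportion >= ``inside_min_frac`` and the mean vertex
    speed <= ``vmax_filter_ms``.
    """
    require_annotated(path)
    n = len(path)
    if n < 2:
        return []
    t = path["t"].to_numpy(dtype=float)
    inside = path["inside_greenspace"].to_numpy(dtype=float)
    speeds = vertex_speeds(path)
    duration = t[-1] - t[0]

    if duration < cfg.ma_window_s:
        if inside.mean() >= cfg.inside_min_frac and speeds.mean() <= cfg.vmax_filter_ms:
            return [path.reset_index(drop=True)]
        return []

    half = cfg.ma_window_s / 2.0
    inside_ma = _window_means(t, inside, half)
    speed_ma = _window_means(t, speeds, half)
    keep = (inside_ma >= cfg.inside_min_frac) & (speed_ma <= cfg.vmax_filter_ms)

    pieces: list[pd.DataFrame] = []
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return pieces
    run_breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, run_breaks):
        if run.size >= 2:
            pieces.append(path.iloc[run].reset_index(drop=True))
    return pieces


def trim_outside_ends(path: pd.DataFrame) -> pd.DataFrame:
    """Leave at most one leading and one trailing outside-boundary vertex."""
    require_annotated(path)
    inside = path["inside_greenspace"].to_numpy(dtype=bool)
    if len(path) == 0:
        return path.reset_index(drop=True)
    where = np.flatnonzero(inside)
    if where.size == 0:
        # fully-outside path (cannot occur after the moving-average filter):
        # keep only the two endpoint vertices
        return path.iloc[sorted({0, len(path) - 1})].reset_index(drop=True)
    start = max(0, int(where[0]) - 1)
    end = min(len(path) - 1, int(where[-1]) + 1)
    return path.iloc[start : end + 1].reset_index(drop=True)


def apply_stage4(
    paths: list[pd.DataFrame], gsmap: GreenspaceMap, cfg: PipelineConfig
) -> list[pd.DataFrame]:
    """Annotate, window-filter, split, trim, and re-check duration.

    Split paths receive suffixed string trip ids (``7 -> "7.1", "7.2"``);
    unsplit survivors keep their id (stringified).  Paths spanning less than
    ``min_trip_duration_s`` after trimming are dropped.
    """
    out: list[pd.DataFrame] = []
    for path in paths:
        ann = annotate(path, gsmap) if "inside_greenspace" not in path.columns else path
        pieces = moving_average_filter(ann, cfg)
        kept = []
        for piece in pieces:
            piece = trim_outside_ends(piece)
            t = piece["t"].to_numpy(dtype=float)
            if len(piece) >= 2 and t[-1] - t[0] >= cfg.min_trip_duration_s:
                kept.append(piece)
        base = str(ann["trip_id"].iloc[0]) if len(ann) else ""
        for i, piece in enumerate(kept):
            piece = piece.copy()
            piece["trip_id"] = f"{base}.{i + 1}" if len(kept) > 1 else base
            out.append(piece)
    return out
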