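"""Coordinate handling and distance primitives.

All pipeline geometry is computed in a single local metric system: a
spherical transverse-Mercator projection centred on the data (or on a
user-supplied origin).  At city scale (tens of km) the distortion of this
projection is far below GPS error; the closed forms are exactly invertible,
so lon/lat round-trips are lossless to floating precision.

Altitude passes through projection unchanged (no geoid correction): the
altitude filter in stage 2 operates on raw reported values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import CRSError, StateError

#: IUGG mean Earth radius, metres
EARTH_RADIUS_M = 6371008.8


class GpsFix(NamedTuple):
    """A single timestamped 3-D position from one device.

    Coordinates are either geographic (``lon``/``lat`` degrees, ``x``/``y``
    None) or projected metres (``x``/``y`` set); ``alt`` is metres above sea
    level and may be any real -- implausible values are filtered in stage 2,
    not rejected at parse.
    """

    device_id: str
    t: float
    lon: float | None = None
    lat: float | None = None
    x: float | None = None
    y: float | None = None
    alt: float = float("nan")

    @property
    def projected(self) -> bool:
        return self.x is not None and self.y is not None


@dataclass(frozen=True)
class LocalMetricCRS:
    """Spherical transverse Mercator centred at (lon0, lat0), in metres."""

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS_M

    @classmethod
    def for_frame(cls, frame: pd.DataFrame) -> "LocalMetricCRS":
        """Centre the projection on the bounding box of a lon/lat frame."""
        if frame.empty:
            return cls(0.0, 0.0)
        lon0 = 0.5 * (frame["lon"].min() + frame["lon"].max())
        lat0 = 0.5 * (frame["lat"].min() + frame["lat"].max())
        return cls(float(lon0), float(lat0))

    def forward(self, lon, lat):
        """Degrees -> metres.  Accepts scalars or arrays."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 89.9) or np.any(np.abs(lon - self.lon0) > 90.0):
            bad = np.argwhere((np.abs(lat) > 89.9) | (np.abs(lon - self.lon0) > 90.0))
            raise CRSError(
                f"coordinates outside projection validity domain at rows {bad.ravel().tolist()}"
            )
        lam = np.radians(lon - self.lon0)
        phi = np.radians(lat)
        b = np.cos(phi) * np.sin(lam)
        x = self.radius * np.arctanh(b)
        y = self.radius * (np.arctan2(np.tan(phi), np.cos(lam)) - math.radians(self.lat0))
        return x, y

    def inverse(self, x, y):
        """Metres -> degrees.  Exact inverse of :meth:`forward`."""
        x = np.asarray(x, dtype=float) / self.radius
        y = np.asarray(y, dtype=float) / self.radius + math.radians(self.lat0)
        phi = np.arcsin(np.sin(y) / np.cosh(x))
        lam = np.arctan2(np.sinh(x), np.cos(y))
        return np.degrees(lam) + self.lon0, np.degrees(phi)


def project(frame: pd.DataFrame, crs: LocalMetricCRS | None = None) -> pd.DataFrame:
    """Add metric ``x``/``y`` columns to a lon/lat fix frame.

    Returns a copy; ``lon``/``lat`` are retained so the original records can
    be reproduced.  An empty frame passes through with empty x/y columns.
    """
    out = frame.copy()
    if crs is None:
        crs = LocalMetricCRS.for_frame(frame)
    if out.empty:
        out["x"] = np.array([], dtype=float)
        out["y"] = np.array([], dtype=float)
        return out
    x, y = crs.forward(out["lon"].to_numpy(), out["lat"].to_numpy())
    out["x"] = x
    out["y"] = y
    return out


def require_projected(frame: pd.DataFrame) -> None:
    if "x" not in frame.columns or "y" not in frame.columns:
        raise StateError("fixes are not projected: run project() first")


def dist3d(a: GpsFix, b: GpsFix) -> float:
    """3-D Euclidean distance (metres) between two projected fixes."""
    if not (a.projected and b.projected):
        raise StateError("dist3d requires projected fixes")
    da = 0.0
    if math.isfinite(a.alt) and math.isfinite(b.alt):
        da = a.alt - b.alt
    return math.hypot(a.x - b.x, a.y - b.y, da)


def step_lengths_3d(frame: pd.DataFrame) -> np.ndarray:
    """3-D lengths of the n-1 steps between consecutive fixes of one trip."""
    require_projected(frame)
    dx = np.diff(frame["x"].to_numpy())
    dy = np.diff(frame["y"].to_numpy())
    alt = frame["alt"].to_numpy(dtype=float)
    dz = np.diff(alt)
    dz = np.where(np.isfinite(dz), dz, 0.0)
    return np.sqrt(dx * dx + dy * dy + dz * dz)


def step_lengths_2d(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Planar lengths of consecutive steps along a vertex sequence."""
    return np.hypot(np.diff(np.asarray(x, float)), np.diff(np.asarray(y, float)))
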