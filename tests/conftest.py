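from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from greentrack import GreenspaceMap, PipelineConfig


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


def make_trip(ts, xs, ys, alts=None, device="dev0", trip_id=0) -> pd.DataFrame:
    """Projected single-trip frame from coordinate lists."""
    ts = np.asarray(ts, dtype=float)
    return pd.DataFrame(
        {
            "device_id": device,
            "trip_id": trip_id,
            "t": ts,
            "x": np.asarray(xs, dtype=float),
            "y": np.asarray(ys, dtype=float),
            "alt": np.full(len(ts), 100.0) if alts is None else np.asarray(alts, dtype=float),
        }
    )


@pytest.fixture
def square_map() -> GreenspaceMap:
    """One 200x200 m park with two entrances and one 20x20 m building."""
    park = Polygon([(0, 0), (200, 0), (200, 200), (0, 200)])
    return GreenspaceMap(
        greenspaces=[("p1", "local park", park)],
        entrances=[("e1", Point(0, 100)), ("e2", Point(200, 100))],
        buildings=[("b1", Polygon([(90, 90), (110, 90), (110, 110), (90, 110)]))],
    )


@pytest.fixture
def two_park_map() -> GreenspaceMap:
    """Two disjoint parks of different types, three entrances, no building."""
    p1 = Polygon([(0, 0), (200, 0), (200, 200), (0, 200)])
    p2 = Polygon([(500, 0), (800, 0), (800, 300), (500, 300)])
    return GreenspaceMap(
        greenspaces=[("p1", "local park", p1), ("p2", "woodland", p2)],
        entrances=[("e1", Point(0, 100)), ("e2", Point(200, 100)), ("e3", Point(500, 150))],
        buildings=[],
    )


def annotate_straight_path(ts, xs, inside, device="dev0", trip_id=0, y=0.0) -> pd.DataFrame:
    """Hand-annotated path along the x-axis (bypasses any map)."""
    n = len(ts)
    return pd.DataFrame(
        {
            "device_id": device,
            "trip_id": trip_id,
            "t": np.asarray(ts, dtype=float),
            "x": np.asarray(xs, dtype=float),
            "y": np.full(n, y, dtype=float),
            "inside_greenspace": np.asarray(inside, dtype=bool),
            "inside_building": np.zeros(n, dtype=bool),
            "greenspace_ids": [("p1",) if i else () for i in inside],
        }
    )
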