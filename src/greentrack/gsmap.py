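"""Greenspace map layers: typed polygons, entrance points, building footprints.

All three layers share one metric coordinate system (the pipeline's local
projection).  Input is GeoJSON FeatureCollections; invalid polygons are
repaired by zero-width buffering (``make_valid``-style) where the repair
preserves area, otherwise rejected with their ids listed.  Point-in-polygon
queries treat the polygon boundary as inside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, mapping, shape
from shapely.strtree import STRtree

from .errors import FormatError
from .projection import LocalMetricCRS

#: default greenspace typology; configurable per map
DEFAULT_TYPOLOGY = (
    "local park",
    "large park",
    "active amenity",
    "visual amenity",
    "civic space",
    "outdoor sports",
    "woodland",
    "allotment",
)


def _repair(geom, gid):
    """Zero-width buffer repair; raise if the result is empty or not areal."""
    warnings.warn(f"repairing invalid polygon {gid!r}", stacklevel=3)
    fixed = shapely.make_valid(geom)
    if fixed.geom_type == "GeometryCollection":
        fixed = shapely.unary_union(
            [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        )
    if fixed.is_empty or fixed.area == 0:
        fixed = geom.buffer(0)
    if fixed.is_empty or not fixed.is_valid or fixed.area == 0:
        raise FormatError(f"polygon {gid!r} is invalid and could not be repaired")
    return fixed


@dataclass
class GreenspaceMap:
    """Greenspace polygons (typed), entrances and buildings in metres."""

    greenspaces: list[tuple[str, str, Polygon]]
    entrances: list[tuple[str, Point]]
    buildings: list[tuple[str, Polygon]]
    crs: LocalMetricCRS | None = None
    typology: tuple[str, ...] = DEFAULT_TYPOLOGY
    _gs_tree: STRtree | None = field(default=None, repr=False, compare=False)
    _bld_tree: STRtree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        repaired = []
        for gid, gtype, geom in self.greenspaces:
            if geom.is_empty:
                raise FormatError(f"greenspace {gid!r} has empty geometry")
            if not geom.is_valid:
                geom = _repair(geom, gid)
            repaired.append((str(gid), str(gtype), geom))
        self.greenspaces = repaired
        self.buildings = [
            (str(bid), g if g.is_valid else _repair(g, bid)) for bid, g in self.buildings
        ]
        self._gs_tree = STRtree([g for _, _, g in self.greenspaces]) if self.greenspaces else None
        self._bld_tree = STRtree([g for _, g in self.buildings]) if self.buildings else None

    # -- queries ----------------------------------------------------------

    def greenspace_membership(self, x, y) -> tuple[np.ndarray, list[tuple[str, ...]]]:
        """For each point: is it inside any greenspace, and which ids.

        Boundary points count as inside (``intersects`` predicate).
        """
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        n = len(pts)
        ids: list[tuple[str, ...]] = [()] * n
        inside = np.zeros(n, dtype=bool)
        if self._gs_tree is None or n == 0:
            return inside, ids
        pi, gi = self._gs_tree.query(pts, predicate="intersects")
        hits: dict[int, list[str]] = {}
        for p, g in zip(pi.tolist(), gi.tolist()):
            hits.setdefault(p, []).append(self.greenspaces[g][0])
        for p, found in hits.items():
            inside[p] = True
            ids[p] = tuple(sorted(found))
        return inside, ids

    def building_membership(self, x, y) -> np.ndarray:
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        inside = np.zeros(len(pts), dtype=bool)
        if self._bld_tree is None or len(pts) == 0:
            return inside
        pi, _ = self._bld_tree.query(pts, predicate="intersects")
        inside[np.unique(pi)] = True
        return inside

    def nearest_entrance_distance(self, x: float, y: float) -> float:
        """Planar distance to the nearest entrance; +inf if none mapped."""
        if not self.entrances:
            return float("inf")
        p = Point(float(x), float(y))
        return min(p.distance(e) for _, e in self.entrances)

    def type_of(self, greenspace_id: str) -> str:
        for gid, gtype, _ in self.greenspaces:
            if gid == greenspace_id:
                return gtype
        raise KeyError(greenspace_id)

    def geofence_region(self, buffer_m: float):
        """Union of greenspaces buffered by the geofence radius."""
        geoms = [g for _, _, g in self.greenspaces]
        return shapely.unary_union([g.buffer(buffer_m) for g in geoms])

    # -- I/O ---------------------------------------------------------------

    def to_geojson(self, greenspace_path, entrance_path=None, building_path=None) -> None:
        def dump(path, feats):
            Path(path).write_text(
                json.dumps({"type": "FeatureCollection", "features": feats})
            )

        dump(
            greenspace_path,
            [
                {"type": "Feature", "properties": {"id": gid, "type": gtype},
                 "geometry": mapping(geom)}
                for gid, gtype, geom in self.greenspaces
            ],
        )
        if entrance_path is not None:
            dump(
                entrance_path,
                [{"type": "Feature", "properties": {"id": eid}, "geometry": mapping(pt)}
                 for eid, pt in self.entrances],
            )
        if building_path is not None:
            dump(
                building_path,
                [{"type": "Feature", "properties": {"id": bid}, "geometry": mapping(geom)}
                 for bid, geom in self.buildings],
            )


def looks_geographic(gsmap: "GreenspaceMap") -> bool:
    """Heuristic: are the map's coordinates lon/lat degrees rather than metres?"""
    xs, ys = [], []
    for _, _, g in gsmap.greenspaces:
        minx, miny, maxx, maxy = g.bounds
        xs += [minx, maxx]
        ys += [miny, maxy]
    if not xs:
        return False
    return max(abs(v) for v in xs) <= 180.0 and max(abs(v) for v in ys) <= 90.0


def transform_map(gsmap: "GreenspaceMap", crs: LocalMetricCRS) -> "GreenspaceMap":
    """Project a geographic-coordinate map into the local metric system."""

    def fwd(coords: np.ndarray) -> np.ndarray:
        x, y = crs.forward(coords[:, 0], coords[:, 1])
        return np.column_stack((x, y))

    return GreenspaceMap(
        greenspaces=[(gid, gt, shapely.transform(g, fwd)) for gid, gt, g in gsmap.greenspaces],
        entrances=[(eid, shapely.transform(p, fwd)) for eid, p in gsmap.entrances],
        buildings=[(bid, shapely.transform(g, fwd)) for bid, g in gsmap.buildings],
        crs=crs,
        typology=gsmap.typology,
    )


def inverse_transform_map(gsmap: "GreenspaceMap", crs: LocalMetricCRS) -> "GreenspaceMap":
    """Back-project a metric map to geographic coordinates (for GeoJSON export)."""

    def inv(coords: np.ndarray) -> np.ndarray:
        lon, lat = crs.inverse(coords[:, 0], coords[:, 1])
        return np.column_stack((lon, lat))

    return GreenspaceMap(
        greenspaces=[(gid, gt, shapely.transform(g, inv)) for gid, gt, g in gsmap.greenspaces],
        entrances=[(eid, shapely.transform(p, inv)) for eid, p in gsmap.entrances],
        buildings=[(bid, shapely.transform(g, inv)) for bid, g in gsmap.buildings],
        crs=None,
        typology=gsmap.typology,
    )


def _load_features(path: str | Path) -> list[dict]:
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection" or "features" not in data:
        raise FormatError(f"{path} is not a GeoJSON FeatureCollection")
    return data["features"]


def read_map(
    greenspace_path: str | Path,
    entrance_path: str | Path | None = None,
    building_path: str | Path | None = None,
    crs: LocalMetricCRS | None = None,
    typology: tuple[str, ...] = DEFAULT_TYPOLOGY,
) -> GreenspaceMap:
    """Load the three GIS layers from GeoJSON (coordinates already metric).

    The entrance and building layers are optional; a missing entrance layer
    is allowed with a warning (entrance-distance attributes then degrade to
    +inf and always raise the incomplete-data flag).
    """
    greenspaces = []
    for feat in _load_features(greenspace_path):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise FormatError(
                f"greenspace feature {props.get('id')!r} has non-polygon geometry "
                f"({geom.geom_type})"
            )
        if "id" not in props or "type" not in props:
            raise FormatError("greenspace features require 'id' and 'type' properties")
        greenspaces.append((props["id"], props["type"], geom))

    entrances = []
    if entrance_path is not None and Path(entrance_path).exists():
        for feat in _load_features(entrance_path):
            geom = shape(feat["geometry"])
            if geom.geom_type != "Point":
                raise FormatError("entrance features must be points")
            entrances.append(((feat.get("properties") or {}).get("id"), geom))
    else:
        warnings.warn(
            "no entrance layer: entrance distances will be +inf and the "
            "incomplete-data flag will always be raised",
            stacklevel=2,
        )

    buildings = []
    if building_path is not None and Path(building_path).exists():
        for feat in _load_features(building_path):
            geom = shape(feat["geometry"])
            if geom.geom_type not in ("Polygon", "MultiPolygon"):
                raise FormatError("building features must be polygons")
            buildings.append(((feat.get("properties") or {}).get("id"), geom))

    return GreenspaceMap(greenspaces, entrances, buildings, crs=crs, typology=typology)
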