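"""Data model and I/O for street networks, parcels, point features, parks and participants.

All geometry lives in a planar projected coordinate system with units of
meters.  The package never reprojects: supplying geographic (longitude /
latitude) coordinates is a contract violation that the loaders detect and
refuse.  GeoJSON is used purely as a geometry *encoding* (RFC 7946 structure,
planar-meter coordinates by convention of this package).

Node identity on street networks is established by coordinate snapping at a
tolerance of 1e-6 m, since GeoJSON carries no topology.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

NODE_SNAP_TOL = 1e-6  # meters; coordinate hashing tolerance for node identity

#: road classes whose edges pedestrians may not traverse (configurable per load)
DEFAULT_NON_WALKABLE_CLASSES = frozenset({"limited_access_highway", "highway_ramp"})

LAND_USE_CLASSES = ("residential", "retail", "civic", "recreational", "other")
POINT_FEATURE_CLASSES = ("transit_stop", "private_recreation")

EDUCATION_LEVELS = ("less_than_high_school", "high_school_or_some_college", "college_or_higher")
MARITAL_STATUSES = ("married_or_partner", "other")
GENDERS = ("female", "male")

#: the five self-reported physical-activity outcomes, with their valid ranges
OUTCOME_RANGES: Mapping[str, tuple[float, float]] = {
    "walk_transport_days": (0.0, 7.0),
    "walk_transport_min": (0.0, math.inf),
    "walk_leisure_days": (0.0, 7.0),
    "walk_leisure_min": (0.0, math.inf),
    "sitting_min": (0.0, math.inf),
}
OUTCOME_NAMES = tuple(OUTCOME_RANGES)

SQM_PER_ACRE = 4046.8564224


class GeoDataError(Exception):
    """Base class for data-contract violations."""


class FormatError(GeoDataError):
    """Input file does not have the expected structure."""


class CoordinateSystemError(GeoDataError):
    """Coordinates look geographic (lon/lat) rather than projected meters."""


class ValidationError(GeoDataError):
    """A feature violates a declared invariant."""


class SchemaError(GeoDataError):
    """A tabular input is missing required columns."""


# ---------------------------------------------------------------------------
# street network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edge:
    """One street centerline segment between two network nodes."""

    id: int
    node_a: int
    node_b: int
    geometry: LineString
    length: float
    walkable: bool
    road_class: str = "street"


@dataclass
class StreetNetwork:
    """Planar embedded street graph: nodes keyed by id, edges carrying polylines.

    The graph may be disconnected and may contain loops and parallel edges.
    """

    nodes: dict[int, tuple[float, float]] = field(default_factory=dict)
    edges: dict[int, Edge] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_length(self, walkable_only: bool = False) -> float:
        return sum(
            e.length for e in self.edges.values() if e.walkable or not walkable_only
        )

    def degrees(self, walkable_only: bool = True) -> dict[int, int]:
        """Node degree counting parallel edges; a loop contributes 2."""
        deg = {nid: 0 for nid in self.nodes}
        for e in self.edges.values():
            if walkable_only and not e.walkable:
                continue
            deg[e.node_a] += 1
            deg[e.node_b] += 1
        return deg

    def to_multigraph(self, walkable_only: bool = True) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for e in sorted(self.edges.values(), key=lambda e: e.id):
            if walkable_only and not e.walkable:
                continue
            g.add_edge(e.node_a, e.node_b, key=e.id, length=e.length)
        return g

    def components(self, walkable_only: bool = True) -> list[set[int]]:
        g = self.to_multigraph(walkable_only=walkable_only)
        return [set(c) for c in nx.connected_components(g)]

    def validate(self) -> None:
        for nid, (x, y) in self.nodes.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValidationError(f"node {nid}: non-finite coordinates")
        for e in self.edges.values():
            if e.length <= 0:
                raise ValidationError(f"edge {e.id}: non-positive length")
            if abs(e.geometry.length - e.length) > 1e-6:
                raise ValidationError(f"edge {e.id}: stored length != polyline arc length")
            for nid, end in ((e.node_a, Point(e.geometry.coords[0])),
                             (e.node_b, Point(e.geometry.coords[-1]))):
                nx_, ny_ = self.nodes[nid]
                if end.distance(Point(nx_, ny_)) > NODE_SNAP_TOL:
                    raise ValidationError(f"edge {e.id}: endpoint does not coincide with node {nid}")


def filter_walkable(net: StreetNetwork) -> StreetNetwork:
    """Return a new network containing only walkable edges and their incident nodes."""
    edges = {eid: e for eid, e in net.edges.items() if e.walkable}
    if not edges:
        logger.warning("filter_walkable: no walkable edges remain")
        return StreetNetwork()
    used = {e.node_a for e in edges.values()} | {e.node_b for e in edges.values()}
    nodes = {nid: xy for nid, xy in net.nodes.items() if nid in used}
    return StreetNetwork(nodes=nodes, edges=edges)


class _NodeIndex:
    """Assigns node ids by coordinate hashing at NODE_SNAP_TOL."""

    def __init__(self) -> None:
        self._by_key: dict[tuple[int, int], int] = {}
        self.nodes: dict[int, tuple[float, float]] = {}

    def get(self, x: float, y: float) -> int:
        key = (round(x / NODE_SNAP_TOL), round(y / NODE_SNAP_TOL))
        nid = self._by_key.get(key)
        if nid is None:
            nid = len(self.nodes)
            self._by_key[key] = nid
            self.nodes[nid] = (x, y)
        return nid


def _looks_geographic(coords: Iterable[tuple[float, float]]) -> bool:
    coords = list(coords)
    if not coords:
        return False
    return all(abs(x) <= 180.0 and abs(y) <= 90.0 for x, y in coords)


def network_from_features(
    features: list[dict],
    non_walkable_classes: frozenset[str] = DEFAULT_NON_WALKABLE_CLASSES,
) -> StreetNetwork:
    """Build a StreetNetwork from GeoJSON LineString features.

    The walkable flag is derived from the ``road_class`` property against a
    deny-list (default: limited-access highways and their ramps, where
    pedestrians are not permitted).
    """
    index = _NodeIndex()
    edges: dict[int, Edge] = {}
    all_coords: list[tuple[float, float]] = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise FormatError(
                f"feature {i}: expected LineString geometry, got {geom.get('type')!r}"
            )
        line = shape(geom)
        all_coords.extend((c[0], c[1]) for c in line.coords)
    if _looks_geographic(all_coords):
        raise CoordinateSystemError(
            "coordinates fall inside lon/lat ranges; planar meter coordinates are required"
        )
    for i, feat in enumerate(features):
        line = shape(feat["geometry"])
        props = feat.get("properties") or {}
        if line.length <= 0:
            raise ValidationError(f"feature {i}: zero-length edge")
        road_class = str(props.get("road_class", "street"))
        eid = int(props.get("edge_id", i))
        (xa, ya), (xb, yb) = line.coords[0], line.coords[-1]
        edges[eid] = Edge(
            id=eid,
            node_a=index.get(xa, ya),
            node_b=index.get(xb, yb),
            geometry=line,
            length=line.length,
            walkable=road_class not in non_walkable_classes,
            road_class=road_class,
        )
    net = StreetNetwork(nodes=dict(index.nodes), edges=edges)
    net.validate()
    return net


def load_network(
    path: str | Path,
    non_walkable_classes: frozenset[str] = DEFAULT_NON_WALKABLE_CLASSES,
) -> StreetNetwork:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    return network_from_features(doc.get("features", []), non_walkable_classes)


def write_network(net: StreetNetwork, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(e.geometry),
            "properties": {"edge_id": e.id, "road_class": e.road_class},
        }
        for e in sorted(net.edges.values(), key=lambda e: e.id)
    ]
    _write_collection(features, path)


def _write_collection(features: list[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# parcels / points / parks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Parcel:
    id: int
    geometry: BaseGeometry
    land_use_class: str
    residential_units: int
    area: float  # full-parcel area snapshot, m^2


@dataclass
class ParcelSet:
    parcels: dict[int, Parcel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.parcels)

    def __iter__(self):
        return iter(sorted(self.parcels.values(), key=lambda p: p.id))


@dataclass(frozen=True)
class PointFeature:
    id: int
    x: float
    y: float
    feature_class: str


@dataclass
class PointFeatureSet:
    points: dict[int, PointFeature] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(sorted(self.points.values(), key=lambda p: p.id))

    def by_class(self, feature_class: str) -> list[PointFeature]:
        return [p for p in self if p.feature_class == feature_class]


@dataclass(frozen=True)
class Park:
    id: int
    geometry: BaseGeometry
    area: float  # m^2


@dataclass
class ParkSet:
    parks: dict[int, Park] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.parks)

    def __iter__(self):
        return iter(sorted(self.parks.values(), key=lambda p: p.id))


def _repaired_polygon(geom: BaseGeometry, label: str) -> BaseGeometry | None:
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    if fixed.is_valid and fixed.area > 0:
        logger.warning("%s: invalid polygon repaired", label)
        return fixed
    logger.warning("%s: invalid polygon could not be repaired; skipped", label)
    return None


def load_parcels(path: str | Path) -> ParcelSet:
    parcels: dict[int, Parcel] = {}
    for i, feat in enumerate(_read_features(path, ("Polygon", "MultiPolygon"))):
        geom = _repaired_polygon(shape(feat["geometry"]), f"parcel feature {i}")
        if geom is None:
            continue
        props = feat.get("properties") or {}
        luc = props.get("land_use_class")
        if luc not in LAND_USE_CLASSES:
            raise ValidationError(f"parcel feature {i}: unknown land_use_class {luc!r}")
        units = int(props.get("residential_units", 0))
        if units < 0:
            raise ValidationError(f"parcel feature {i}: negative residential_units")
        if units > 0 and luc != "residential":
            raise ValidationError(
                f"parcel feature {i}: residential_units > 0 on non-residential parcel"
            )
        if geom.area <= 0:
            raise ValidationError(f"parcel feature {i}: zero-area polygon")
        pid = int(props.get("parcel_id", i))
        parcels[pid] = Parcel(pid, geom, luc, units, float(props.get("area_m2", geom.area)))
    return ParcelSet(parcels)


def write_parcels(parcels: ParcelSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.geometry),
            "properties": {
                "parcel_id": p.id,
                "land_use_class": p.land_use_class,
                "residential_units": p.residential_units,
                "area_m2": p.area,
            },
        }
        for p in parcels
    ]
    _write_collection(features, path)


def load_points(path: str | Path) -> PointFeatureSet:
    points: dict[int, PointFeature] = {}
    for i, feat in enumerate(_read_features(path, ("Point",))):
        x, y = feat["geometry"]["coordinates"][:2]
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValidationError(f"point feature {i}: non-finite coordinates")
        props = feat.get("properties") or {}
        fc = props.get("feature_class")
        if fc not in POINT_FEATURE_CLASSES:
            raise ValidationError(f"point feature {i}: unknown feature_class {fc!r}")
        pid = int(props.get("point_id", i))
        points[pid] = PointFeature(pid, float(x), float(y), fc)
    return PointFeatureSet(points)


def write_points(points: PointFeatureSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
            "properties": {"point_id": p.id, "feature_class": p.feature_class},
        }
        for p in points
    ]
    _write_collection(features, path)


def load_parks(path: str | Path) -> ParkSet:
    parks: dict[int, Park] = {}
    for i, feat in enumerate(_read_features(path, ("Polygon", "MultiPolygon"))):
        geom = _repaired_polygon(shape(feat["geometry"]), f"park feature {i}")
        if geom is None:
            continue
        if geom.area <= 0:
            raise ValidationError(f"park feature {i}: zero-area polygon")
        props = feat.get("properties") or {}
        pid = int(props.get("park_id", i))
        parks[pid] = Park(pid, geom, float(props.get("area_m2", geom.area)))
    return ParkSet(parks)


def write_parks(parks: ParkSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.geometry),
            "properties": {"park_id": p.id, "area_m2": p.area},
        }
        for p in parks
    ]
    _write_collection(features, path)


def _read_features(path: str | Path, allowed_types: tuple[str, ...]) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    feats = doc.get("features", [])
    for i, feat in enumerate(feats):
        gtype = (feat.get("geometry") or {}).get("type")
        if gtype not in allowed_types:
            raise FormatError(
                f"{path}: feature {i} has geometry {gtype!r}, expected one of {allowed_types}"
            )
    return feats


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

PARTICIPANT_COLUMNS = (
    "participant_id", "x", "y", "age", "gender", "education", "marital_status",
    "employed", "cluster_id", "ses_stratum", "walkability_stratum", "city",
) + OUTCOME_NAMES


@dataclass(frozen=True)
class Participant:
    """One cohort member: home location, covariates, strata, and the five outcomes."""

    id: str
    x: float
    y: float
    age: float
    gender: str
    education: str
    marital_status: str
    employed: bool
    cluster_id: str
    ses_stratum: str
    walkability_stratum: str
    city: str
    outcomes: dict[str, float]

    def validate(self, check_ranges: bool = True) -> None:
        if not self.cluster_id:
            raise ValidationError(f"participant {self.id}: empty cluster_id")
        checks = (
            (self.gender, GENDERS, "gender"),
            (self.education, EDUCATION_LEVELS, "education"),
            (self.marital_status, MARITAL_STATUSES, "marital_status"),
            (self.ses_stratum, ("low", "high"), "ses_stratum"),
            (self.walkability_stratum, ("low", "high"), "walkability_stratum"),
        )
        for value, vocab, name in checks:
            if value not in vocab:
                raise ValidationError(f"participant {self.id}: {name}={value!r} not in {vocab}")
        if not check_ranges:
            return
        for name, (lo, hi) in OUTCOME_RANGES.items():
            v = self.outcomes[name]
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"participant {self.id}: outcome {name}={v} outside [{lo}, {hi}]"
                )


def participants_from_frame(df: pd.DataFrame) -> list[Participant]:
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"participant table missing columns: {missing}")
    out: list[Participant] = []
    for _, row in df.iterrows():
        p = Participant(
            id=str(row["participant_id"]),
            x=float(row["x"]),
            y=float(row["y"]),
            age=float(row["age"]),
            gender=str(row["gender"]),
            education=str(row["education"]),
            marital_status=str(row["marital_status"]),
            employed=bool(row["employed"]) if not isinstance(row["employed"], str)
            else row["employed"].lower() in ("true", "1", "yes"),
            cluster_id=str(row["cluster_id"]),
            ses_stratum=str(row["ses_stratum"]),
            walkability_stratum=str(row["walkability_stratum"]),
            city=str(row["city"]),
            outcomes={name: float(row[name]) for name in OUTCOME_NAMES},
        )
        p.validate()
        out.append(p)
    return out


def load_participants(path: str | Path) -> list[Participant]:
    return participants_from_frame(pd.read_csv(path))


def participants_to_frame(participants: list[Participant]) -> pd.DataFrame:
    rows = []
    for p in participants:
        row = {
            "participant_id": p.id, "x": p.x, "y": p.y, "age": p.age,
            "gender": p.gender, "education": p.education,
            "marital_status": p.marital_status, "employed": p.employed,
            "cluster_id": p.cluster_id, "ses_stratum": p.ses_stratum,
            "walkability_stratum": p.walkability_stratum, "city": p.city,
        }
        row.update(p.outcomes)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS))


def write_participants(participants: list[Participant], path: str | Path) -> None:
    participants_to_frame(participants).to_csv(path, index=False)
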