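"""Network service areas: snap a home location to the street network and find
the sub-network reachable within a shortest-path distance cutoff.

The reach computation is a single-source Dijkstra expansion in which the
origin splits its host edge in two.  Every walkable edge then contributes the
portion of its length whose network distance from the origin does not exceed
the cutoff; an edge reachable from both endpoints contributes the union of
its two partial reaches.  Within an edge there are no junctions, so the
network distance to an interior point at arc offset ``s`` on edge ``(u, v)``
of length ``L`` is ``min(d(u) + s, d(v) + L - s)`` (plus, on the origin's own
edge, the direct distance from the origin) — making per-edge reached
intervals exact, not discretized.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from shapely.geometry import LineString, Point, mapping
from shapely.ops import substring

from .geodata import GeoDataError, StreetNetwork

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 1000.0  # meters: 10-15 minute walk, the conventional home-neighborhood scale
DEFAULT_MAX_SNAP = 500.0  # meters; beyond this a warning is recorded

_TOL = 1e-9


class ServiceAreaError(GeoDataError):
    pass


@dataclass(frozen=True)
class NetworkLocation:
    """A point constrained to the street network."""

    edge_id: int
    offset: float  # meters from edge's node_a along the polyline
    x: float
    y: float
    snap_distance: float


@dataclass
class ReachSegment:
    edge_id: int
    from_offset: float
    to_offset: float
    geometry: LineString

    @property
    def length(self) -> float:
        return self.to_offset - self.from_offset


@dataclass
class ReachedSubnetwork:
    origin: NetworkLocation
    cutoff: float
    segments: list[ReachSegment] = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.segments)

    @property
    def is_empty(self) -> bool:
        return not self.segments

    def geometries(self) -> list[LineString]:
        return [s.geometry for s in self.segments]


def snap_to_network(
    point: tuple[float, float],
    net: StreetNetwork,
    max_snap_distance: float = DEFAULT_MAX_SNAP,
) -> NetworkLocation:
    """Snap a point to the nearest location on any walkable edge (Euclidean).

    Ties are broken by lowest edge id, then lowest offset, so results are
    reproducible on symmetric geometry.
    """
    p = Point(point)
    best: tuple[float, int, float] | None = None
    for eid in sorted(net.edges):
        e = net.edges[eid]
        if not e.walkable:
            continue
        off = e.geometry.project(p)
        d = e.geometry.distance(p)
        cand = (d, eid, off)
        if best is None or cand < best:
            best = cand
    if best is None:
        raise ServiceAreaError("cannot snap: network has no walkable edges")
    d, eid, off = best
    snapped = net.edges[eid].geometry.interpolate(off)
    if d > max_snap_distance:
        logger.warning(
            "snap distance %.1f m exceeds %.1f m for point (%.1f, %.1f)",
            d, max_snap_distance, point[0], point[1],
        )
    return NetworkLocation(edge_id=eid, offset=off, x=snapped.x, y=snapped.y, snap_distance=d)


def _node_distances(net: StreetNetwork, origin: NetworkLocation, cutoff: float) -> dict[int, float]:
    """Dijkstra node distances from a mid-edge origin, truncated at cutoff."""
    adjacency: dict[int, list[tuple[float, int, int]]] = {}
    for eid in sorted(net.edges):
        e = net.edges[eid]
        if not e.walkable:
            continue
        adjacency.setdefault(e.node_a, []).append((e.length, eid, e.node_b))
        adjacency.setdefault(e.node_b, []).append((e.length, eid, e.node_a))

    host = net.edges[origin.edge_id]
    heap: list[tuple[float, int]] = []
    heapq.heappush(heap, (origin.offset, host.node_a))
    heapq.heappush(heap, (host.length - origin.offset, host.node_b))
    dist: dict[int, float] = {}
    while heap:
        d, u = heapq.heappop(heap)
        if u in dist or d > cutoff:
            continue
        dist[u] = d
        for length, _eid, v in adjacency.get(u, ()):
            nd = d + length
            if nd <= cutoff and v not in dist:
                heapq.heappush(heap, (nd, v))
    return dist


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1] + _TOL:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged if hi - lo > _TOL]


def reachable_subnetwork(
    net: StreetNetwork,
    origin: NetworkLocation,
    cutoff: float = DEFAULT_CUTOFF,
) -> ReachedSubnetwork:
    """All full and partial walkable edge segments within ``cutoff`` network
    meters of the origin."""
    if cutoff <= 0:
        raise ServiceAreaError(f"cutoff must be positive, got {cutoff}")
    host = net.edges.get(origin.edge_id)
    if host is None:
        raise ServiceAreaError(f"origin edge {origin.edge_id} not in network")
    if not host.walkable:
        raise ServiceAreaError(f"origin lies on non-walkable edge {origin.edge_id}")
    if not (-_TOL <= origin.offset <= host.length + _TOL):
        raise ServiceAreaError("origin offset outside its host edge")

    dist = _node_distances(net, origin, cutoff)
    segments: list[ReachSegment] = []
    for eid in sorted(net.edges):
        e = net.edges[eid]
        if not e.walkable:
            continue
        intervals: list[tuple[float, float]] = []
        budget_a = cutoff - dist.get(e.node_a, float("inf"))
        budget_b = cutoff - dist.get(e.node_b, float("inf"))
        if budget_a > 0:
            intervals.append((0.0, min(e.length, budget_a)))
        if budget_b > 0:
            intervals.append((max(0.0, e.length - budget_b), e.length))
        if eid == origin.edge_id:
            intervals.append(
                (max(0.0, origin.offset - cutoff), min(e.length, origin.offset + cutoff))
            )
        for lo, hi in _merge_intervals(intervals):
            geom = substring(e.geometry, lo, hi)
            segments.append(ReachSegment(eid, lo, hi, geom))
    if not segments:
        # cutoff smaller than any reach is impossible on the host edge, so this
        # only happens on degenerate geometry
        logger.warning("empty reach for origin on edge %d", origin.edge_id)
    return ReachedSubnetwork(origin=origin, cutoff=cutoff, segments=segments)


def reach_to_geojson_features(reach: ReachedSubnetwork, participant_id: str) -> list[dict]:
    """Reached segments as GeoJSON LineString features tagged with the participant id."""
    return [
        {
            "type": "Feature",
            "geometry": mapping(s.geometry),
            "properties": {
                "participant_id": participant_id,
                "edge_id": s.edge_id,
                "from_offset": s.from_offset,
                "to_offset": s.to_offset,
            },
        }
        for s in reach.segments
    ]
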