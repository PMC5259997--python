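"""Shared fixtures: tiny hand-built street networks and independent oracles."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest
from shapely.geometry import LineString

from bufcomp.geodata import Edge, StreetNetwork
from bufcomp.service_area import NetworkLocation, ReachedSubnetwork


def make_network(lines: list[list[tuple[float, float]]],
                 road_classes: list[str] | None = None) -> StreetNetwork:
    """Build a StreetNetwork directly from polylines (endpoint snapping)."""
    road_classes = road_classes or ["street"] * len(lines)
    key_to_node: dict[tuple[int, int], int] = {}
    nodes: dict[int, tuple[float, float]] = {}
    edges: dict[int, Edge] = {}
    for eid, (coords, rc) in enumerate(zip(lines, road_classes)):
        geom = LineString(coords)
        endpoints = []
        for x, y in (coords[0], coords[-1]):
            key = (round(x * 1e6), round(y * 1e6))
            if key not in key_to_node:
                nid = len(nodes)
                key_to_node[key] = nid
                nodes[nid] = (x, y)
            endpoints.append(key_to_node[key])
        edges[eid] = Edge(eid, endpoints[0], endpoints[1], geom, geom.length,
                          rc not in ("limited_access_highway", "highway_ramp"), rc)
    net = StreetNetwork(nodes=nodes, edges=edges)
    net.validate()
    return net


@pytest.fixture
def straight_road() -> StreetNetwork:
    """One 4 km straight street along the x axis."""
    return make_network([[(0.0, 0.0), (4000.0, 0.0)]])


@pytest.fixture
def plus_network() -> StreetNetwork:
    """Four 1500 m arms meeting at a central degree-4 node."""
    c = (2000.0, 2000.0)
    return make_network([
        [c, (3500.0, 2000.0)],
        [c, (500.0, 2000.0)],
        [c, (2000.0, 3500.0)],
        [c, (2000.0, 500.0)],
    ])


def ladder_network(block: float = 300.0, n_blocks: int = 4) -> StreetNetwork:
    """Two parallel streets connected by evenly spaced rungs (enclosed blocks)."""
    lines = []
    width = block
    for y in (0.0, width):
        for i in range(n_blocks):
            lines.append([(i * block, y), ((i + 1) * block, y)])
    for i in range(n_blocks + 1):
        lines.append([(i * block, 0.0), (i * block, width)])
    return make_network(lines)


@pytest.fixture
def ladder() -> StreetNetwork:
    return ladder_network()


def node_location(net: StreetNetwork, node_id: int) -> NetworkLocation:
    """A NetworkLocation exactly at a node, on its lowest-id incident edge."""
    for eid in sorted(net.edges):
        e = net.edges[eid]
        if e.node_a == node_id:
            x, y = net.nodes[node_id]
            return NetworkLocation(eid, 0.0, x, y, 0.0)
        if e.node_b == node_id:
            x, y = net.nodes[node_id]
            return NetworkLocation(eid, e.length, x, y, 0.0)
    raise ValueError(f"node {node_id} has no incident edge")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def densified_reach_length(net: StreetNetwork, origin: NetworkLocation, cutoff: float,
                           step: float = 1.0) -> float:
    """Brute-force service-area length: Dijkstra on a graph densified into
    ~1 m stations, with per-unit-link reached measure computed from the two
    station distances.  Independent of the production per-edge interval code.
    """
    g = nx.Graph()
    station_of: dict[tuple[int, int], object] = {}
    links: list[tuple[object, object, float]] = []
    for eid in sorted(net.edges):
        e = net.edges[eid]
        if not e.walkable:
            continue
        n_units = max(1, int(round(e.length / step)))
        unit = e.length / n_units
        prev = ("n", e.node_a)
        for k in range(1, n_units):
            cur = ("s", eid, k)
            station_of[(eid, k)] = cur
            links.append((prev, cur, unit))
            prev = cur
        links.append((prev, ("n", e.node_b), unit))
    for u, v, w in links:
        if g.has_edge(u, v):
            w = min(w, g[u][v]["weight"])
        g.add_edge(u, v, weight=w)

    host = net.edges[origin.edge_id]
    n_units = max(1, int(round(host.length / step)))
    unit = host.length / n_units
    k = origin.offset / unit
    lo_k = min(int(np.floor(k)), n_units - 1)
    src = "origin"
    lo = ("n", host.node_a) if lo_k == 0 else station_of[(origin.edge_id, lo_k)]
    hi = ("n", host.node_b) if lo_k + 1 >= n_units else station_of[(origin.edge_id, lo_k + 1)]
    g.add_edge(src, lo, weight=origin.offset - lo_k * unit)
    g.add_edge(src, hi, weight=(lo_k + 1) * unit - origin.offset)

    dist = nx.single_source_dijkstra_path_length(g, src, cutoff=cutoff, weight="weight")
    total = 0.0
    for u, v, w in links:
        du = dist.get(u, np.inf)
        dv = dist.get(v, np.inf)
        a = min(max(cutoff - du, 0.0), w)
        b = min(max(cutoff - dv, 0.0), w)
        total += min(w, a + b)
    return total


def monte_carlo_area(geom, n_samples: int = 1_000_000, seed: int = 0) -> float:
    """Point-in-union area estimate over the geometry's bounding box."""
    import shapely

    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = geom.bounds
    xs = rng.uniform(minx, maxx, n_samples)
    ys = rng.uniform(miny, maxy, n_samples)
    inside = shapely.contains_xy(geom, xs, ys)
    return inside.mean() * (maxx - minx) * (maxy - miny)


def full_reach(net: StreetNetwork, origin: NetworkLocation) -> ReachedSubnetwork:
    """Reach covering the whole component (cutoff beyond any distance)."""
    from bufcomp.service_area import reachable_subnetwork

    return reachable_subnetwork(net, origin, cutoff=net.total_length() + 1.0)
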