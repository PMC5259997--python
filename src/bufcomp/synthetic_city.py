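"""Synthetic cities and cohorts with the statistical structure the analysis assumes.

The generator produces a pruned street grid (one connectivity parameter spans
the low- to high-walkability contrast), land-use parcels tiling block
interiors, transit/recreation points scattered along streets, block-sized
parks, and a participant cohort whose five self-reported physical-activity
outcomes are drawn from a latent Gaussian model:

    latent = intercept + beta_w * z(true walkability) + covariate terms
             + cluster intercept ~ N(0, sigma_c^2) + N(0, sigma_e^2)

mapped to each outcome's support (days/week: rounded and clamped to 0–7;
minutes/week: exponential link).  "True" walkability used for outcome
generation is measured in a large fixed circular window around the home, so
no network-buffer method is privileged by construction.  Everything is
deterministic under the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.prepared import prep

from .geodata import (
    EDUCATION_LEVELS,
    GENDERS,
    MARITAL_STATUSES,
    OUTCOME_NAMES,
    Edge,
    Parcel,
    ParcelSet,
    Park,
    ParkSet,
    Participant,
    PointFeature,
    PointFeatureSet,
    StreetNetwork,
    filter_walkable,
)

CITY_LABEL = "synthville"


class GenerationError(Exception):
    pass


@dataclass
class CityConfig:
    """Physical layout of a synthetic city.

    Defaults describe a mid-density town: a 12 x 12 grid of 120 m blocks
    (~37 km of street), 15% of interior street segments removed, a small
    share of limited-access highway, mixed land use dominated by housing, and
    transit/recreation destinations at realistic suburban intensities
    (roughly one stop per 2 km of street).
    """

    grid_blocks: tuple[int, int] = (12, 12)
    block_size: float = 120.0
    edge_prune_prob: float = 0.15
    limited_access_fraction: float = 0.05
    origin: tuple[float, float] = (1000.0, 1000.0)
    category_shares: dict[str, float] = field(
        default_factory=lambda: {
            "residential": 0.55, "retail": 0.15, "civic": 0.10,
            "recreational": 0.10, "other": 0.10,
        }
    )
    units_per_residential_parcel_mean: float = 20.0
    parcel_margin: float = 10.0
    parcels_per_block_side: int = 2
    point_intensity_per_km: dict[str, float] = field(
        default_factory=lambda: {"transit_stop": 0.5, "private_recreation": 0.3}
    )
    point_offset_range: tuple[float, float] = (2.0, 30.0)
    park_block_prob: float = 0.06
    true_walkability_radius: float = 800.0
    max_retries: int = 100

    def validate(self) -> None:
        if self.block_size <= 0:
            raise GenerationError("block_size must be positive")
        for name, p in (("edge_prune_prob", self.edge_prune_prob),
                        ("limited_access_fraction", self.limited_access_fraction)):
            if not 0 <= p < 1:
                raise GenerationError(f"{name} must be in [0, 1)")
        if abs(sum(self.category_shares.values()) - 1) > 1e-9:
            raise GenerationError("category_shares must sum to 1")


@dataclass
class OutcomeModelConfig:
    """Latent-Gaussian outcome model parameters.

    ``beta_walkability`` is the effect of one sample-sd of true walkability on
    the latent scale.  Transport-walking outcomes respond most strongly,
    leisure weakly, and sitting slightly negatively, echoing the usual
    pattern in walkability studies.  Cluster and residual sds are on the
    latent scale shared by all outcomes.
    """

    intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "walk_transport_days": 3.0,
            "walk_transport_min": 4.7,   # log scale; exp ~ 110 min/week
            "walk_leisure_days": 2.0,
            "walk_leisure_min": 4.3,
            "sitting_min": 7.7,          # log scale; exp ~ 2200 min/week
        }
    )
    beta_walkability: dict[str, float] = field(
        default_factory=lambda: {
            "walk_transport_days": 0.30,
            "walk_transport_min": 0.30,
            "walk_leisure_days": 0.10,
            "walk_leisure_min": 0.10,
            "sitting_min": -0.15,
        }
    )
    families: dict[str, str] = field(
        default_factory=lambda: {
            "walk_transport_days": "days",
            "walk_transport_min": "log_minutes",
            "walk_leisure_days": "days",
            "walk_leisure_min": "log_minutes",
            "sitting_min": "log_minutes",
        }
    )
    age_effect: float = -0.005      # per year from the age-42 reference
    female_effect: float = -0.10
    education_effect: float = 0.10  # per ordered education level
    married_effect: float = 0.05
    employed_effect: float = 0.10
    cluster_sd: float = 0.5
    residual_sd: float = 1.0

    def validate(self) -> None:
        if self.cluster_sd < 0 or self.residual_sd < 0:
            raise GenerationError("standard deviations must be non-negative")


def generate_network(cfg: CityConfig, seed: int | np.random.Generator = 0) -> StreetNetwork:
    """Pruned-grid street network; retries pruning until the walkable part is
    connected, so participants can always be placed on one component."""
    cfg.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m, n = cfg.grid_blocks
    bs, (x0, y0) = cfg.block_size, cfg.origin

    def node_xy(i: int, j: int) -> tuple[float, float]:
        return (x0 + i * bs, y0 + j * bs)

    candidates: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for i in range(m + 1):
        for j in range(n + 1):
            if i < m:
                candidates.append(((i, j), (i + 1, j)))
            if j < n:
                candidates.append(((i, j), (i, j + 1)))

    for _ in range(cfg.max_retries):
        keep = rng.random(len(candidates)) >= cfg.edge_prune_prob
        limited = rng.random(len(candidates)) < cfg.limited_access_fraction
        node_ids: dict[tuple[int, int], int] = {}
        nodes: dict[int, tuple[float, float]] = {}
        edges: dict[int, Edge] = {}
        eid = 0
        for k, (a, b) in enumerate(candidates):
            if not keep[k]:
                continue
            for ij in (a, b):
                if ij not in node_ids:
                    nid = len(node_ids)
                    node_ids[ij] = nid
                    nodes[nid] = node_xy(*ij)
            road_class = "limited_access_highway" if limited[k] else "street"
            geom = LineString([node_xy(*a), node_xy(*b)])
            edges[eid] = Edge(eid, node_ids[a], node_ids[b], geom, geom.length,
                              road_class == "street", road_class)
            eid += 1
        net = StreetNetwork(nodes=nodes, edges=edges)
        walkable = filter_walkable(net)
        if walkable.n_edges and len(walkable.components()) == 1:
            return net
    raise GenerationError(
        f"could not produce a connected walkable network in {cfg.max_retries} tries"
    )


def _block_polygon(cfg: CityConfig, i: int, j: int, margin: float) -> Polygon:
    bs, (x0, y0) = cfg.block_size, cfg.origin
    return Polygon([
        (x0 + i * bs + margin, y0 + j * bs + margin),
        (x0 + (i + 1) * bs - margin, y0 + j * bs + margin),
        (x0 + (i + 1) * bs - margin, y0 + (j + 1) * bs - margin),
        (x0 + i * bs + margin, y0 + (j + 1) * bs - margin),
    ])


def generate_features(
    net: StreetNetwork, cfg: CityConfig, seed: int | np.random.Generator = 0
) -> tuple[ParcelSet, PointFeatureSet, ParkSet]:
    """Parcels tiling block interiors, points along walkable streets, parks on
    random blocks."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m, n = cfg.grid_blocks
    categories = list(cfg.category_shares)
    shares = np.array([cfg.category_shares[c] for c in categories])

    parcels: dict[int, Parcel] = {}
    pid = 0
    k = cfg.parcels_per_block_side
    for i in range(m):
        for j in range(n):
            block = _block_polygon(cfg, i, j, cfg.parcel_margin)
            minx, miny, maxx, maxy = block.bounds
            dx, dy = (maxx - minx) / k, (maxy - miny) / k
            for a in range(k):
                for b in range(k):
                    poly = Polygon([
                        (minx + a * dx, miny + b * dy),
                        (minx + (a + 1) * dx, miny + b * dy),
                        (minx + (a + 1) * dx, miny + (b + 1) * dy),
                        (minx + a * dx, miny + (b + 1) * dy),
                    ])
                    cat = categories[rng.choice(len(categories), p=shares)]
                    units = 0
                    if cat == "residential":
                        units = 1 + int(rng.poisson(max(cfg.units_per_residential_parcel_mean - 1, 0)))
                    parcels[pid] = Parcel(pid, poly, cat, units, poly.area)
                    pid += 1

    walkable_edges = sorted(
        (e for e in net.edges.values() if e.walkable), key=lambda e: e.id
    )
    lengths = np.array([e.length for e in walkable_edges])
    total_km = lengths.sum() / 1000.0
    points: dict[int, PointFeature] = {}
    ptid = 0
    lo, hi = cfg.point_offset_range
    for fclass in sorted(cfg.point_intensity_per_km):
        count = int(rng.poisson(cfg.point_intensity_per_km[fclass] * total_km))
        for _ in range(count):
            e = walkable_edges[rng.choice(len(walkable_edges), p=lengths / lengths.sum())]
            t = rng.uniform(0, e.length)
            on_road = e.geometry.interpolate(t)
            # unit normal to the (straight) grid segment
            (xa, ya), (xb, yb) = e.geometry.coords[0], e.geometry.coords[-1]
            nxv, nyv = -(yb - ya) / e.length, (xb - xa) / e.length
            off = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
            points[ptid] = PointFeature(ptid, on_road.x + nxv * off, on_road.y + nyv * off, fclass)
            ptid += 1

    parks: dict[int, Park] = {}
    kid = 0
    for i in range(m):
        for j in range(n):
            if rng.random() < cfg.park_block_prob:
                poly = _block_polygon(cfg, i, j, cfg.parcel_margin)
                parks[kid] = Park(kid, poly, poly.area)
                kid += 1
    return ParcelSet(parcels), PointFeatureSet(points), ParkSet(parks)


def true_walkability(
    homes: np.ndarray,
    net: StreetNetwork,
    parcels: ParcelSet,
    radius: float,
) -> np.ndarray:
    """Walkability score from a fixed circular window around each home:
    z(intersection density) + z(net residential density) + z(land-use entropy).

    The circular window is deliberately method-neutral: it is not any of the
    network buffers under comparison.
    """
    from shapely.strtree import STRtree

    degrees = net.degrees(walkable_only=True)
    inter_xy = np.array(
        [net.nodes[nid] for nid, d in degrees.items() if d >= 3], dtype=float
    ).reshape(-1, 2)
    cats = ("residential", "retail", "civic", "recreational")
    parcel_list = list(parcels)
    tree = STRtree([p.geometry for p in parcel_list])
    comp = np.zeros((len(homes), 3))
    for h, (hx, hy) in enumerate(homes):
        circle = Point(hx, hy).buffer(radius, quad_segs=16)
        prepared = prep(circle)
        if len(inter_xy):
            d2 = (inter_xy[:, 0] - hx) ** 2 + (inter_xy[:, 1] - hy) ** 2
            n_inter = int((d2 <= radius**2).sum())
        else:
            n_inter = 0
        area_by_cat = dict.fromkeys(cats, 0.0)
        res_units, res_area = 0, 0.0
        for idx in sorted(tree.query(circle)):
            p = parcel_list[idx]
            if prepared.intersects(p.geometry):
                if p.land_use_class in area_by_cat:
                    area_by_cat[p.land_use_class] += p.area
                if p.land_use_class == "residential":
                    res_units += p.residential_units
                    res_area += p.area
        total = sum(area_by_cat.values())
        present = [a for a in area_by_cat.values() if a > 0]
        if total > 0 and len(present) > 1:
            ent = -sum((a / total) * math.log(a / total) for a in present) / math.log(len(cats))
        else:
            ent = 0.0
        comp[h] = (n_inter / (circle.area / 1e6),
                   res_units / (res_area / 1e6) if res_area > 0 else 0.0,
                   ent)
    z = np.zeros_like(comp)
    for c in range(comp.shape[1]):
        sd = comp[:, c].std(ddof=1)
        z[:, c] = (comp[:, c] - comp[:, c].mean()) / sd if sd > 0 else 0.0
    return z.sum(axis=1)


def _spatial_clusters(homes: np.ndarray, n_clusters: int) -> list[str]:
    """Contiguous cluster labels from a rectangular partition of the home extent."""
    ncx = max(1, math.ceil(math.sqrt(n_clusters)))
    ncy = max(1, math.ceil(n_clusters / ncx))
    minx, miny = homes.min(axis=0)
    maxx, maxy = homes.max(axis=0)
    spanx = max(maxx - minx, 1e-9)
    spany = max(maxy - miny, 1e-9)
    labels = []
    for hx, hy in homes:
        cx = min(int((hx - minx) / spanx * ncx), ncx - 1)
        cy = min(int((hy - miny) / spany * ncy), ncy - 1)
        labels.append(f"c{min(cx * ncy + cy, n_clusters - 1):03d}")
    return labels


def generate_cohort(
    net: StreetNetwork,
    parcels: ParcelSet,
    n: int,
    n_clusters: int,
    outcome_cfg: OutcomeModelConfig | None = None,
    cfg: CityConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[Participant], np.ndarray]:
    """Cohort with homes near streets, contiguous clusters, SES x walkability
    strata, and model-generated outcomes.  Returns (participants, true
    walkability z-sums) — the latter is the generating exposure, useful for
    parameter-recovery checks."""
    if not (n >= n_clusters >= 1):
        raise GenerationError("need n >= n_clusters >= 1")
    outcome_cfg = outcome_cfg or OutcomeModelConfig()
    outcome_cfg.validate()
    cfg = cfg or CityConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    walkable = filter_walkable(net)
    comp = max(walkable.components(), key=len)
    edges = sorted(
        (e for e in walkable.edges.values() if e.node_a in comp), key=lambda e: e.id
    )
    lengths = np.array([e.length for e in edges])
    homes = np.zeros((n, 2))
    for h in range(n):
        e = edges[rng.choice(len(edges), p=lengths / lengths.sum())]
        t = rng.uniform(0, e.length)
        pt = e.geometry.interpolate(t)
        (xa, ya), (xb, yb) = e.geometry.coords[0], e.geometry.coords[-1]
        nxv, nyv = -(yb - ya) / e.length, (xb - xa) / e.length
        off = rng.uniform(5.0, 40.0) * (1 if rng.random() < 0.5 else -1)
        homes[h] = (pt.x + nxv * off, pt.y + nyv * off)

    walk_z = true_walkability(homes, net, parcels, cfg.true_walkability_radius)
    sdw = walk_z.std(ddof=1)
    walk_z = (walk_z - walk_z.mean()) / sdw if sdw > 0 else walk_z

    # smooth SES field: random linear gradient plus idiosyncratic noise
    theta = rng.uniform(0, 2 * math.pi)
    proj = homes[:, 0] * math.cos(theta) + homes[:, 1] * math.sin(theta)
    sproj = proj.std(ddof=1)
    ses_score = (proj - proj.mean()) / (sproj if sproj > 0 else 1.0) + rng.normal(0, 0.5, n)
    ses = np.where(ses_score >= np.median(ses_score), "high", "low")
    walk_stratum = np.where(walk_z >= np.median(walk_z), "high", "low")

    cluster_ids = _spatial_clusters(homes, n_clusters)
    cluster_labels = sorted(set(cluster_ids))

    ages = rng.uniform(18, 66, n)
    genders = rng.choice(GENDERS, n, p=[0.53, 0.47])
    education = rng.choice(EDUCATION_LEVELS, n, p=[0.15, 0.45, 0.40])
    marital = rng.choice(MARITAL_STATUSES, n, p=[0.60, 0.40])
    employed = rng.random(n) < 0.78

    participants: list[Participant] = []
    outcome_values: dict[str, np.ndarray] = {}
    for name in OUTCOME_NAMES:
        cl_eff = dict(zip(cluster_labels,
                          rng.normal(0, outcome_cfg.cluster_sd, len(cluster_labels))))
        eps = rng.normal(0, outcome_cfg.residual_sd, n)
        edu_idx = np.array([EDUCATION_LEVELS.index(e) for e in education], dtype=float)
        lp = (
            outcome_cfg.intercepts[name]
            + outcome_cfg.beta_walkability[name] * walk_z
            + outcome_cfg.age_effect * (ages - 42.0)
            + outcome_cfg.female_effect * (genders == "female")
            + outcome_cfg.education_effect * edu_idx
            + outcome_cfg.married_effect * (marital == "married_or_partner")
            + outcome_cfg.employed_effect * employed
            + np.array([cl_eff[c] for c in cluster_ids])
            + eps
        )
        family = outcome_cfg.families[name]
        if family == "days":
            outcome_values[name] = np.clip(np.round(lp), 0, 7)
        elif family == "log_minutes":
            outcome_values[name] = np.exp(lp)
        elif family == "identity":
            outcome_values[name] = lp
        else:
            raise GenerationError(f"unknown outcome family {family!r}")

    for h in range(n):
        p = Participant(
            id=f"p{h:04d}",
            x=float(homes[h, 0]), y=float(homes[h, 1]),
            age=float(ages[h]), gender=str(genders[h]), education=str(education[h]),
            marital_status=str(marital[h]), employed=bool(employed[h]),
            cluster_id=cluster_ids[h],
            ses_stratum=str(ses[h]), walkability_stratum=str(walk_stratum[h]),
            city=CITY_LABEL,
            outcomes={name: float(outcome_values[name][h]) for name in OUTCOME_NAMES},
        )
        # the identity family is a diagnostic mode whose values live on the
        # latent scale, outside the native outcome supports
        native = all(f != "identity" for f in outcome_cfg.families.values())
        p.validate(check_ranges=native)
        participants.append(p)
    return participants, walk_z


@dataclass
class SyntheticCity:
    net: StreetNetwork
    parcels: ParcelSet
    points: PointFeatureSet
    parks: ParkSet
    participants: list[Participant]
    true_walkability_z: np.ndarray


def generate_city(
    n: int = 400,
    n_clusters: int = 20,
    cfg: CityConfig | None = None,
    outcome_cfg: OutcomeModelConfig | None = None,
    seed: int = 0,
) -> SyntheticCity:
    """One call, the whole dataset: network, features, cohort."""
    cfg = cfg or CityConfig()
    rng = np.random.default_rng(seed)
    net = generate_network(cfg, rng)
    parcels, points, parks = generate_features(net, cfg, rng)
    participants, walk_z = generate_cohort(
        net, parcels, n, n_clusters, outcome_cfg, cfg, rng
    )
    return SyntheticCity(net, parcels, points, parks, participants, walk_z)


def write_city(city: SyntheticCity, outdir) -> dict[str, str]:
    """Write the full dataset as GeoJSON + CSV; returns the file map."""
    from pathlib import Path

    from . import geodata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "network": "network.geojson",
        "parcels": "parcels.geojson",
        "points": "points.geojson",
        "parks": "parks.geojson",
        "participants": "participants.csv",
    }
    geodata.write_network(city.net, outdir / files["network"])
    geodata.write_parcels(city.parcels, outdir / files["parcels"])
    geodata.write_points(city.points, outdir / files["points"])
    geodata.write_parks(city.parks, outdir / files["parks"])
    geodata.write_participants(city.participants, outdir / files["participants"])
    return files
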