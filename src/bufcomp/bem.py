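"""The eleven built-environment measures (BEMs) computed per participant and
buffer polygon.

Measure definitions follow the common walkability literature:

* net residential density — residential units per km² of *residential parcel
  land* (not total buffer area);
* intersection count/density — walkable street nodes of degree ≥ 3 inside
  the buffer, and their density per km² of buffer;
* transit stop and private recreation access — counts (optionally after
  snapping the points to the street network) and densities per km² of buffer;
* public park access — count of intersecting parks and the sum of their full
  areas;
* land use mix — normalized Shannon entropy of land-area shares across the
  configured land-use categories, on a 0–1 scale;
* walkability index — sum of sample z-scores of net residential density,
  land use mix and intersection density.

Polygon features (parcels, parks) are assigned to a buffer if *any* portion
of their geometry intersects it, and contribute their full area and unit
count; this whole-feature rule means a parcel on the buffer fringe counts
the same as one at its center.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .buffers import BufferPolygon
from .geodata import (
    SQM_PER_ACRE,
    ParcelSet,
    ParkSet,
    PointFeatureSet,
    StreetNetwork,
)
from .service_area import snap_to_network

logger = logging.getLogger(__name__)

DEFAULT_LUM_CATEGORIES = ("residential", "retail", "civic", "recreational")

BEM_COLUMNS = (
    "res_density",
    "intersection_count",
    "intersection_density",
    "transit_count",
    "transit_density",
    "recreation_count",
    "recreation_density",
    "park_count",
    "park_area_sum",
    "land_use_mix",
    "walk_index",
)

#: BEM component columns entering the walkability index
WALK_INDEX_COMPONENTS = ("res_density", "land_use_mix", "intersection_density")


class BemError(Exception):
    pass


def assign_polygons(buffer: BufferPolygon, polygons: ParcelSet | ParkSet) -> list[int]:
    """Ids of polygon features whose geometry intersects the buffer (shared
    boundary counts)."""
    prepared = prep(buffer.geometry)
    included = []
    for feat in polygons:
        if prepared.intersects(feat.geometry):
            included.append(feat.id)
    return included


def snap_points(points: PointFeatureSet, net: StreetNetwork) -> dict[int, tuple[float, float]]:
    """Snapped coordinates for every point feature (network-nearest location)."""
    out = {}
    for p in points:
        loc = snap_to_network((p.x, p.y), net)
        out[p.id] = (loc.x, loc.y)
    return out


def count_snapped_points(
    buffer: BufferPolygon,
    points: PointFeatureSet,
    net: StreetNetwork | None = None,
    snapped: bool = True,
    snapped_coords: dict[int, tuple[float, float]] | None = None,
) -> dict[str, int]:
    """Count point features inside or on the buffer boundary, per feature class.

    With ``snapped=True`` each point is first relocated to its nearest point
    on the walkable street network, so destinations that sit just off the
    roadway (parking lots, set-back entrances) are captured by narrow
    buffers.  Both modes are supported; precomputed snapped coordinates may
    be passed to avoid re-snapping per buffer.
    """
    if snapped and snapped_coords is None:
        if net is None:
            raise BemError("snapped counting requires a street network")
        snapped_coords = snap_points(points, net)
    prepared = prep(buffer.geometry)
    counts: dict[str, int] = {}
    for p in points:
        xy = snapped_coords[p.id] if snapped else (p.x, p.y)
        if prepared.intersects(Point(xy)):
            counts[p.feature_class] = counts.get(p.feature_class, 0) + 1
    return counts


def net_residential_density(
    buffer: BufferPolygon, parcels: ParcelSet, included_ids: list[int] | None = None
) -> tuple[float, bool]:
    """Residential units per km² of included residential parcel land.

    Returns ``(density, missing_denominator)``; density is 0 with the flag set
    when the buffer contains no residential parcels.
    """
    if included_ids is None:
        included_ids = assign_polygons(buffer, parcels)
    units = 0
    area_m2 = 0.0
    for pid in included_ids:
        p = parcels.parcels[pid]
        if p.land_use_class == "residential":
            units += p.residential_units
            area_m2 += p.area
    if area_m2 <= 0:
        return 0.0, True
    return units / (area_m2 / 1e6), False


def intersection_metrics(
    buffer: BufferPolygon, net: StreetNetwork, min_degree: int = 3
) -> tuple[int, float]:
    """Count and per-km² density of walkable street intersections inside the
    buffer.  An intersection is a node of degree ≥ ``min_degree`` on the
    walkable network."""
    degrees = net.degrees(walkable_only=True)
    prepared = prep(buffer.geometry)
    count = 0
    for nid, deg in degrees.items():
        if deg >= min_degree and prepared.intersects(Point(net.nodes[nid])):
            count += 1
    return count, count / (buffer.area / 1e6)


def land_use_mix(
    buffer: BufferPolygon,
    parcels: ParcelSet,
    included_ids: list[int] | None = None,
    categories: tuple[str, ...] = DEFAULT_LUM_CATEGORIES,
) -> float:
    """Normalized entropy of included full-parcel land areas over ``categories``.

    Shares are taken over the configured k categories only (parcels in other
    classes are excluded); the denominator is ln k regardless of how many
    categories are present, so a buffer missing some uses scores below 1.
    Returns 0 when at most one category is present.
    """
    if included_ids is None:
        included_ids = assign_polygons(buffer, parcels)
    areas = dict.fromkeys(categories, 0.0)
    for pid in included_ids:
        p = parcels.parcels[pid]
        if p.land_use_class in areas:
            areas[p.land_use_class] += p.area
    total = sum(areas.values())
    present = [a for a in areas.values() if a > 0]
    if total <= 0 or len(present) <= 1:
        return 0.0
    k = len(categories)
    entropy = -sum((a / total) * math.log(a / total) for a in present)
    return entropy / math.log(k)


def park_metrics(
    buffer: BufferPolygon, parks: ParkSet, included_ids: list[int] | None = None
) -> tuple[int, float]:
    """Count of intersecting parks and the sum of their full areas in m²."""
    if included_ids is None:
        included_ids = assign_polygons(buffer, parks)
    return len(included_ids), sum(parks.parks[pid].area for pid in included_ids)


def park_area_to_acres(area_m2: float) -> float:
    return area_m2 / SQM_PER_ACRE


def walkability_index(bem_rows: pd.DataFrame, ddof: int = 1) -> pd.Series:
    """Per-participant walkability index for one (method, trim) group of rows.

    Sum of z-scores (sample mean 0, sd 1) of net residential density, land
    use mix and intersection density, standardized across the analysis
    sample.  Raises when a component has zero variance, since its z-score is
    undefined.
    """
    if len(bem_rows) < 2:
        raise BemError("walkability index needs at least 2 participants")
    index = pd.Series(0.0, index=bem_rows.index)
    for col in WALK_INDEX_COMPONENTS:
        values = bem_rows[col].to_numpy(dtype=float)
        sd = values.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise BemError(f"walkability index: component {col!r} has zero variance")
        index += (values - values.mean()) / sd
    return index


@dataclass
class BemContext:
    """Shared inputs for BEM computation over a cohort."""

    net: StreetNetwork
    parcels: ParcelSet
    points: PointFeatureSet
    parks: ParkSet
    snapped: bool = True
    min_intersection_degree: int = 3
    lum_categories: tuple[str, ...] = DEFAULT_LUM_CATEGORIES


def compute_bem_row(buffer: BufferPolygon, ctx: BemContext,
                    snapped_coords: dict[int, tuple[float, float]] | None = None) -> dict:
    """All per-buffer BEMs for one participant (walk_index added later, sample-wide)."""
    parcel_ids = assign_polygons(buffer, ctx.parcels)
    park_ids = assign_polygons(buffer, ctx.parks)
    res_density, res_missing = net_residential_density(buffer, ctx.parcels, parcel_ids)
    icount, idensity = intersection_metrics(buffer, ctx.net, ctx.min_intersection_degree)
    counts = count_snapped_points(
        buffer, ctx.points, ctx.net, snapped=ctx.snapped, snapped_coords=snapped_coords
    )
    area_km2 = buffer.area / 1e6
    transit = counts.get("transit_stop", 0)
    recreation = counts.get("private_recreation", 0)
    park_count, park_area = park_metrics(buffer, ctx.parks, park_ids)
    return {
        "participant_id": buffer.participant_id,
        "method": buffer.method,
        "trim": buffer.trim,
        "buffer_area_m2": buffer.area,
        "res_density": res_density,
        "res_density_missing_denominator": res_missing,
        "intersection_count": icount,
        "intersection_density": idensity,
        "transit_count": transit,
        "transit_density": transit / area_km2,
        "recreation_count": recreation,
        "recreation_density": recreation / area_km2,
        "park_count": park_count,
        "park_area_sum": park_area,
        "land_use_mix": land_use_mix(buffer, ctx.parcels, parcel_ids, ctx.lum_categories),
    }


def compute_bem_table(buffers: list[BufferPolygon], ctx: BemContext) -> pd.DataFrame:
    """Tidy BEM table keyed by (participant_id, method, trim), walk_index included.

    The walkability index is standardized separately within each
    (method, trim) group, i.e. across the analysis sample for that buffer
    configuration.
    """
    snapped_coords = snap_points(ctx.points, ctx.net) if ctx.snapped else None
    rows = [compute_bem_row(b, ctx, snapped_coords) for b in buffers]
    df = pd.DataFrame(rows)
    df["walk_index"] = np.nan
    for (_method, _trim), group in df.groupby(["method", "trim"]):
        df.loc[group.index, "walk_index"] = walkability_index(group)
    return df.sort_values(["method", "trim", "participant_id"]).reset_index(drop=True)
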