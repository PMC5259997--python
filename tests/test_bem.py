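"""Built-environment measure correctness against closed forms and exhaustive oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon

from bufcomp.bem import (
    BemContext,
    BemError,
    assign_polygons,
    compute_bem_table,
    count_snapped_points,
    intersection_metrics,
    land_use_mix,
    net_residential_density,
    park_metrics,
    walkability_index,
)
from bufcomp.buffers import BufferPolygon, build_buffers, sausage_buffer
from bufcomp.geodata import (
    Parcel,
    ParcelSet,
    Park,
    ParkSet,
    PointFeature,
    PointFeatureSet,
    filter_walkable,
)
from bufcomp.service_area import reachable_subnetwork, snap_to_network
from bufcomp.synthetic_city import generate_city

from .conftest import make_network


def square(cx, cy, half):
    return Polygon([(cx - half, cy - half), (cx + half, cy - half),
                    (cx + half, cy + half), (cx - half, cy + half)])


def parcel_set(specs):
    """specs: list of (geometry, land_use_class, units)."""
    return ParcelSet({
        i: Parcel(i, g, c, u, g.area) for i, (g, c, u) in enumerate(specs)
    })


@pytest.fixture
def road_buffer(straight_road):
    loc = snap_to_network((2000.0, 0.0), straight_road)
    reach = reachable_subnetwork(straight_road, loc, 1000.0)
    return sausage_buffer(reach, 25.0, "p0")


class TestPolygonAssignment:
    def test_whole_feature_rule(self, road_buffer):
        parks = ParkSet({
            0: Park(0, square(2000, 0, 10), 400.0),          # wholly inside
            1: Park(1, square(2000, 124, 100), 40000.0),     # 1 m overlap at the fringe
            2: Park(2, square(2000, 200, 50), 10000.0),      # well outside
        })
        ids = assign_polygons(road_buffer, parks)
        assert ids == [0, 1]
        count, area = park_metrics(road_buffer, parks, ids)
        assert count == 2
        # the fringe park counts with its FULL area
        assert area == pytest.approx(400.0 + 40000.0)

    def test_boundary_touch_counts(self, road_buffer):
        parks = ParkSet({0: Park(0, square(2000, 75, 50), 10000.0)})  # touches y=25
        assert assign_polygons(road_buffer, parks) == [0]


class TestResidentialDensity:
    def test_arithmetic(self, road_buffer):
        parcels = parcel_set([
            (square(1500, 0, 100), "residential", 120),
            (square(2500, 0, 100), "residential", 80),
            (square(2000, 0, 100), "retail", 0),
        ])
        # 200 units on 2 * (200 m)^2 = 0.08 km^2
        density, missing = net_residential_density(road_buffer, parcels)
        assert not missing
        assert density == pytest.approx(200 / 0.08)

    def test_linearity_in_units(self, road_buffer):
        specs = [(square(1500, 0, 100), "residential", 120),
                 (square(2500, 0, 100), "residential", 80)]
        d1, _ = net_residential_density(road_buffer, parcel_set(specs))
        doubled = [(g, c, 2 * u) for g, c, u in specs]
        d2, _ = net_residential_density(road_buffer, parcel_set(doubled))
        assert d2 == pytest.approx(2 * d1)

    def test_no_residential_parcels_flagged(self, road_buffer):
        parcels = parcel_set([(square(2000, 0, 100), "retail", 0)])
        density, missing = net_residential_density(road_buffer, parcels)
        assert density == 0.0 and missing


class TestIntersections:
    def test_plus_center_counts_once(self, plus_network):
        loc = snap_to_network((2000.0, 2000.0), plus_network)
        reach = reachable_subnetwork(plus_network, loc, 1000.0)
        buf = sausage_buffer(reach, 25.0)
        count, density = intersection_metrics(buf, plus_network)
        assert count == 1
        assert density == pytest.approx(1 / (buf.area / 1e6))

    def test_straight_road_has_none(self, road_buffer, straight_road):
        assert intersection_metrics(road_buffer, straight_road)[0] == 0

    def test_grid_city_matches_brute_force(self):
        city = generate_city(n=3, n_clusters=2, seed=7)
        net = filter_walkable(city.net)
        p = city.participants[0]
        loc = snap_to_network((p.x, p.y), net)
        reach = reachable_subnetwork(net, loc, 1000.0)
        buf = sausage_buffer(reach, 25.0, p.id)
        count, _ = intersection_metrics(buf, net)
        deg = net.degrees(walkable_only=True)
        brute = sum(
            1 for nid, d in deg.items()
            if d >= 3 and buf.geometry.intersects(Point(net.nodes[nid]))
        )
        assert count == brute


class TestPointCounting:
    def test_snapping_captures_setback_stop(self, road_buffer, straight_road):
        """A stop 40 m off the road misses the 25 m sausage unsnapped but is
        captured once snapped to the network."""
        points = PointFeatureSet({0: PointFeature(0, 2000.0, 40.0, "transit_stop")})
        unsnapped = count_snapped_points(road_buffer, points, snapped=False)
        snapped = count_snapped_points(road_buffer, points, straight_road, snapped=True)
        assert unsnapped.get("transit_stop", 0) == 0
        assert snapped["transit_stop"] == 1

    def test_point_in_unreached_part_not_counted(self, road_buffer, straight_road):
        # snaps to x=3500, outside the reach [1000, 3000] buffer
        points = PointFeatureSet({0: PointFeature(0, 3500.0, 30.0, "transit_stop")})
        counts = count_snapped_points(road_buffer, points, straight_road, snapped=True)
        assert counts.get("transit_stop", 0) == 0

    def test_zero_points(self, road_buffer, straight_road):
        counts = count_snapped_points(road_buffer, PointFeatureSet({}), straight_road)
        assert counts == {}

    def test_snapped_at_least_unsnapped_near_network(self, straight_road, road_buffer):
        """Points within the trim of the reached street: snapping never loses them."""
        rng = np.random.default_rng(0)
        pts = {
            i: PointFeature(i, float(rng.uniform(1100, 2900)),
                            float(rng.uniform(-24, 24)), "transit_stop")
            for i in range(20)
        }
        pset = PointFeatureSet(pts)
        snapped = count_snapped_points(road_buffer, pset, straight_road, snapped=True)
        unsnapped = count_snapped_points(road_buffer, pset, snapped=False)
        assert snapped["transit_stop"] >= unsnapped.get("transit_stop", 0)


class TestLandUseMix:
    def test_equal_shares_max_entropy(self, road_buffer):
        parcels = parcel_set([
            (square(1500, 0, 50), "residential", 1),
            (square(1700, 0, 50), "retail", 0),
            (square(1900, 0, 50), "civic", 0),
            (square(2100, 0, 50), "recreational", 0),
        ])
        assert land_use_mix(road_buffer, parcels) == pytest.approx(1.0)

    def test_single_category_zero(self, road_buffer):
        parcels = parcel_set([(square(1500, 0, 50), "retail", 0)])
        assert land_use_mix(road_buffer, parcels) == 0.0

    def test_two_equal_of_four_is_half(self, road_buffer):
        parcels = parcel_set([
            (square(1500, 0, 50), "residential", 1),
            (square(1700, 0, 50), "retail", 0),
        ])
        assert land_use_mix(road_buffer, parcels) == pytest.approx(
            math.log(2) / math.log(4)
        )

    def test_other_class_excluded(self, road_buffer):
        parcels = parcel_set([
            (square(1500, 0, 50), "residential", 1),
            (square(1700, 0, 50), "other", 0),
        ])
        assert land_use_mix(road_buffer, parcels) == 0.0

    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           a=st.floats(min_value=1.0, max_value=100.0),
           b=st.floats(min_value=1.0, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_uniform_area_scaling(self, scale, a, b):
        """Entropy depends only on area shares, so scaling all areas is a no-op."""
        pa = np.array([a, b])

        def lum(areas):
            p = areas / areas.sum()
            return -(p * np.log(p)).sum() / math.log(4)

        assert lum(pa) == pytest.approx(lum(pa * scale), rel=1e-9)


class TestWalkabilityIndex:
    def make_rows(self, values):
        return pd.DataFrame(values, columns=["res_density", "land_use_mix",
                                             "intersection_density"])

    def test_sample_mean_zero_and_unit_sd(self):
        rng = np.random.default_rng(1)
        rows = self.make_rows(rng.uniform(size=(40, 3)) * [5000, 1, 80])
        idx = walkability_index(rows)
        assert idx.mean() == pytest.approx(0.0, abs=1e-9)
        for col in rows.columns:
            z = (rows[col] - rows[col].mean()) / rows[col].std(ddof=1)
            assert z.std(ddof=1) == pytest.approx(1.0)

    def test_participant_at_means_scores_zero(self):
        base = self.make_rows([[1000.0, 0.2, 30.0], [3000.0, 0.6, 70.0]])
        mid = self.make_rows([[2000.0, 0.4, 50.0]])
        rows = pd.concat([base, mid], ignore_index=True)
        assert walkability_index(rows).iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_zsums(self):
        rows = self.make_rows([
            [1000.0, 0.1, 20.0], [2000.0, 0.3, 40.0], [1500.0, 0.5, 60.0],
            [4000.0, 0.2, 30.0], [2500.0, 0.9, 90.0],
        ])
        expected = np.zeros(5)
        for col in rows.columns:
            v = rows[col].to_numpy()
            expected += (v - v.mean()) / v.std(ddof=1)
        assert walkability_index(rows).to_numpy() == pytest.approx(expected)

    def test_zero_variance_component_raises(self):
        rows = self.make_rows([[1.0, 0.5, 20.0], [2.0, 0.5, 40.0]])
        with pytest.raises(BemError, match="land_use_mix"):
            walkability_index(rows)


class TestBemTable:
    def test_counts_nondecreasing_across_nested_buffers(self):
        """Buffers are nested sausage ⊆ DT ⊆ detailed, so counts never drop."""
        city = generate_city(n=4, n_clusters=2, seed=13)
        net = filter_walkable(city.net)
        buffers = []
        for p in city.participants:
            loc = snap_to_network((p.x, p.y), net)
            reach = reachable_subnetwork(net, loc, 1000.0)
            buffers.extend(build_buffers(reach, p.id, 25.0).values())
        ctx = BemContext(net, city.parcels, city.points, city.parks)
        table = compute_bem_table(buffers, ctx)
        order = {"sausage": 0, "detailed_trimmed": 1, "detailed": 2}
        for pid, grp in table.groupby("participant_id"):
            grp = grp.sort_values("method", key=lambda s: s.map(order))
            for col in ("intersection_count", "transit_count", "recreation_count",
                        "park_count", "park_area_sum"):
                vals = grp[col].to_numpy()
                assert (np.diff(vals) >= 0).all(), (pid, col, vals)

    def test_densities_recompute_from_counts(self):
        city = generate_city(n=4, n_clusters=2, seed=13)
        net = filter_walkable(city.net)
        buffers = []
        for p in city.participants:
            loc = snap_to_network((p.x, p.y), net)
            reach = reachable_subnetwork(net, loc, 1000.0)
            buffers.extend(build_buffers(reach, p.id, 25.0).values())
        table = compute_bem_table(buffers, BemContext(net, city.parcels,
                                                      city.points, city.parks))
        area_km2 = table["buffer_area_m2"] / 1e6
        for count_col, dens_col in [("intersection_count", "intersection_density"),
                                    ("transit_count", "transit_density"),
                                    ("recreation_count", "recreation_density")]:
            np.testing.assert_allclose(
                table[dens_col], table[count_col] / area_km2, rtol=1e-9
            )
        assert table["land_use_mix"].between(0, 1).all()
        for (_m, _t), grp in table.groupby(["method", "trim"]):
            assert grp["walk_index"].mean() == pytest.approx(0.0, abs=1e-9)
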