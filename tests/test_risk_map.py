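"""Ring buffers, risk schemes, and overlap escalation."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from rotadist.risk_map import (
    QUAD_SEGS,
    RiskScheme,
    RiskZone,
    build_buffers,
    build_risk_map,
    flatten_with_escalation,
    grain_pea_scheme,
    green_pea_scheme,
    nearest_distance,
)
from rotadist.synthetic_landscape import LandscapeSpec, generate_fields, split_by_year
from rotadist.vector_io import FieldSite

from conftest import make_layer
from _oracles import brute_force_boundary_distance, pointwise_class


class TestRiskScheme:
    def test_default_grain_scheme(self):
        s = grain_pea_scheme()
        assert s.distances_m == (1261, 1560, 1825)
        assert s.classes == (4, 2, 1)
        assert s.ladder == (1, 2, 4, 8)
        assert s.cap == 8

    def test_default_green_scheme_single_500m_band(self):
        s = green_pea_scheme()
        assert s.distances_m == (500,)
        assert len(s.classes) == 1

    def test_next_class_ladder_steps_and_cap(self):
        s = grain_pea_scheme()
        assert s.next_class(2) == 4
        assert s.next_class(4) == 8
        assert s.next_class(8) == 8  # saturates
        assert s.next_class(1, steps=2) == 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(distances_m=(100, 100), classes=(2, 1)),  # non-increasing distances
            dict(distances_m=(200, 100), classes=(2, 1)),
            dict(distances_m=(100, 200), classes=(1, 2)),  # classes increase outward
            dict(distances_m=(100,), classes=(3,)),  # 3 not on ladder 1,2,4,8
            dict(distances_m=(), classes=()),
        ],
    )
    def test_invalid_schemes_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RiskScheme(**kwargs)

    def test_linear_ladder_supported(self):
        s = RiskScheme(distances_m=(100, 200), classes=(2, 1), ladder=(1, 2, 3, 4))
        assert s.next_class(2) == 3


class TestNearestDistance:
    def test_touching_squares_distance_zero(self, make_square_layer):
        prev = make_square_layer([(0, 0)], half=0.5)
        site = FieldSite(
            id="x", geometry=Polygon([(0.5, 0), (1.5, 0), (1.5, 1), (0.5, 1)]), year=2016
        )
        assert nearest_distance(site, prev) == 0.0

    def test_axis_aligned_gap(self):
        prev = make_layer([Polygon([(30, 0), (40, 0), (40, 10), (30, 10)])])
        site = FieldSite(id="x", geometry=Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]), year=2016)
        assert nearest_distance(site, prev) == pytest.approx(20.0)

    def test_only_nearest_site_matters(self, make_square_layer):
        prev = make_square_layer([(300, 0), (5000, 0)])
        site = FieldSite(id="x", geometry=Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]), year=2016)
        assert nearest_distance(site, prev) == pytest.approx(300 - 50 - 10)

    def test_empty_previous_layer_raises(self, unit_square_site):
        with pytest.raises(ValueError, match="empty"):
            nearest_distance(unit_square_site, make_layer([]))

    def test_matches_densified_vertex_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a = _random_quad(rng, cx=0, cy=0)
            b = _random_quad(rng, cx=rng.uniform(150, 400), cy=rng.uniform(-200, 200))
            prev = make_layer([b])
            site = FieldSite(id="x", geometry=a, year=2016)
            exact = nearest_distance(site, prev)
            brute = brute_force_boundary_distance(a, b)
            assert abs(exact - brute) <= 0.5


def _random_quad(rng, cx, cy, scale=60.0):
    pts = [(cx + rng.uniform(-scale, scale), cy + rng.uniform(-scale, scale)) for _ in range(4)]
    from shapely.geometry import MultiPoint

    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":
        return Polygon([(cx, cy), (cx + 30, cy), (cx + 30, cy + 30)])
    return hull


class TestBuildBuffers:
    def test_square_field_three_ring_arithmetic(self, make_square_layer):
        prev = make_square_layer([(0, 0)])
        scheme = grain_pea_scheme()
        zones = build_buffers(prev, scheme)
        assert len(zones) == 3
        geom = prev.sites[0].geometry
        b = [geom.buffer(d, quad_segs=QUAD_SEGS) for d in (1261, 1560, 1825)]
        assert zones[0].geometry.area == pytest.approx(b[0].area, rel=1e-12)
        assert zones[1].geometry.area == pytest.approx(b[1].area - b[0].area, rel=1e-9)
        assert zones[2].geometry.area == pytest.approx(b[2].area - b[1].area, rel=1e-9)
        assert [z.risk_class for z in zones] == [4, 2, 1]
        assert [z.band_m for z in zones] == [1261, 1560, 1825]

    def test_innermost_zone_contains_source_polygon(self, make_square_layer):
        prev = make_square_layer([(0, 0)])
        zones = build_buffers(prev, grain_pea_scheme())
        assert zones[0].geometry.contains(prev.sites[0].geometry)

    def test_circular_field_annulus_closed_form(self):
        r, d = 200.0, 500.0
        circle = Point(0, 0).buffer(r, quad_segs=64)
        prev = make_layer([circle])
        scheme = RiskScheme(distances_m=(d,), classes=(4,))
        (zone,) = build_buffers(prev, scheme)
        expected = math.pi * (r + d) ** 2
        # chordal approximation undershoots the true disc slightly
        assert zone.geometry.area == pytest.approx(expected, rel=5e-3)
        assert zone.geometry.area <= expected

    def test_translation_invariance_of_band_areas(self, make_square_layer):
        prev = make_square_layer([(0, 0), (50_000, 0)])
        zones = build_buffers(prev, grain_pea_scheme())
        by_source = {}
        for z in zones:
            by_source.setdefault(z.source_id, []).append(z.geometry.area)
        a0, a1 = by_source.values()
        assert a0 == pytest.approx(a1, rel=1e-12)

    def test_per_crop_schemes_in_mixed_landscape(self, make_square_layer):
        grain = make_square_layer([(0, 0)], crop="grain_pea")
        green = make_square_layer([(50_000, 0)], crop="green_pea")
        layer = make_layer([])
        layer.sites = grain.sites + green.sites
        zones = build_buffers(layer, per_crop=True)
        bands = sorted({z.band_m for z in zones})
        assert bands == [500, 1261, 1560, 1825]


class TestFlattenWithEscalation:
    def test_two_class2_overlap_escalates_to_class4(self, make_square_layer):
        # two sources whose class-2 middle rings overlap -> next exponential class
        prev = make_square_layer([(0, 0), (2900, 0)])
        rmap = build_risk_map(prev, per_crop=False)
        cls = rmap.class_at(1450, 0)
        assert cls == 4
        zone = [z for z in rmap.zones if z.geometry.covers(Point(1450, 0))]
        assert any(z.escalated for z in zone)

    def test_single_source_identity(self, make_square_layer):
        prev = make_square_layer([(0, 0)])
        zones = build_buffers(prev, grain_pea_scheme())
        rmap = flatten_with_escalation(zones, grain_pea_scheme())
        assert sorted(z.risk_class for z in rmap.zones) == [1, 2, 4]
        assert not any(z.escalated for z in rmap.zones)
        in_areas = sorted(z.geometry.area for z in zones)
        out_areas = sorted(z.geometry.area for z in rmap.zones)
        for a, b in zip(in_areas, out_areas):
            assert a == pytest.approx(b, rel=1e-9)

    def test_three_overlapping_top_class_saturates_at_cap(self):
        scheme = RiskScheme(distances_m=(100,), classes=(8,))
        zones = [
            RiskZone(Point(x, 0).buffer(100, quad_segs=16), 8, 100, source_id=f"s{i}")
            for i, x in enumerate((0, 50, 100))
        ]
        rmap = flatten_with_escalation(zones, scheme)
        assert {z.risk_class for z in rmap.zones} == {8}

    def test_mixed_class_overlap_escalates_from_max(self, make_square_layer):
        # inner band (class 4) of one source over middle band (class 2) of the
        # other: escalation starts at the worse class -> 8
        prev = make_square_layer([(0, 0), (2500, 0)])
        rmap = build_risk_map(prev, per_crop=False)
        # 1200 m from A's edge (class 4 band), 1150 m from B's edge (class 4): 8
        # choose a point in A band0 and B band1: distance to A <=1261, to B in (1261,1560]
        pt = (1100, 0)  # dA = 1050 (band0), dB = 2500-50-1100 = 1350 (band1)
        assert rmap.class_at(*pt) == 8
        oracle_cls, ambiguous = pointwise_class(pt, prev, grain_pea_scheme())
        assert not ambiguous and oracle_cls == 8

    def test_per_source_step_mode_climbs_one_rung_per_extra_source(self):
        scheme = RiskScheme(distances_m=(100,), classes=(2,))
        zones = [
            RiskZone(Point(x, 0).buffer(100, quad_segs=16), 2, 100, source_id=f"s{i}")
            for i, x in enumerate((0, 40, 80))
        ]
        one = flatten_with_escalation(zones, scheme, mode="one-step")
        per = flatten_with_escalation(zones, scheme, mode="per-source-step")
        assert one.class_at(40, 0) == 4  # one ladder step regardless of count
        assert per.class_at(40, 0) == 8  # 3 sources -> 2 steps: 2 -> 4 -> 8

    def test_flatness_pairwise_disjoint_interiors(self, make_square_layer):
        prev = make_square_layer([(0, 0), (2000, 500), (1000, -1500)])
        rmap = build_risk_map(prev, per_crop=False)
        zones = rmap.zones
        for i in range(len(zones)):
            for j in range(i + 1, len(zones)):
                inter = zones[i].geometry.intersection(zones[j].geometry)
                assert inter.area < 1e-6

    def test_area_conservation_under_flattening(self, make_square_layer):
        prev = make_square_layer([(0, 0), (2000, 500), (1000, -1500)])
        zones = build_buffers(prev, grain_pea_scheme())
        rmap = flatten_with_escalation(zones, grain_pea_scheme())
        in_union = unary_union([z.geometry for z in zones])
        assert rmap.union.area == pytest.approx(in_union.area, rel=1e-6)

    def test_monotone_escalation_never_lowers_class(self, make_square_layer):
        prev = make_square_layer([(0, 0), (1500, 0), (0, 1500)])
        zones = build_buffers(prev, grain_pea_scheme())
        rmap = flatten_with_escalation(zones, grain_pea_scheme())
        rng = np.random.default_rng(4)
        for _ in range(200):
            x, y = rng.uniform(-2000, 3500, 2)
            pt = Point(x, y)
            covering = [z.risk_class for z in zones if z.geometry.covers(pt)]
            if covering:
                assert rmap.class_at(x, y) >= max(covering)

    def test_idempotent_when_treated_as_single_source(self, make_square_layer):
        prev = make_square_layer([(0, 0), (2900, 0)])
        rmap = build_risk_map(prev, per_crop=False)
        again = flatten_with_escalation(rmap.zones, rmap.scheme)  # source_id now None
        def by_class(m):
            areas = {}
            for z in m.zones:
                areas[z.risk_class] = areas.get(z.risk_class, 0.0) + z.geometry.area
            return areas
        a, b = by_class(rmap), by_class(again)
        assert set(a) == set(b)
        for cls in a:
            assert a[cls] == pytest.approx(b[cls], rel=1e-9)

    def test_pointwise_oracle_agreement_on_random_landscape(self):
        spec = LandscapeSpec(n_fields=10, region_diameter_m=10_000, seed=21, years=(2015,))
        prev = split_by_year(generate_fields(spec), 2015)
        rmap = build_risk_map(prev, per_crop=False)
        scheme = grain_pea_scheme()
        rng = np.random.default_rng(22)
        checked = 0
        for _ in range(400):
            x = rng.uniform(-7000, 7000)
            y = rng.uniform(-7000, 7000)
            expected, ambiguous = pointwise_class((x, y), prev, scheme)
            if ambiguous:
                continue
            assert rmap.class_at(x, y) == expected, (x, y)
            checked += 1
        assert checked > 300
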