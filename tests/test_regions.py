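"""Geometry: Douglas-Peucker oracle checks, merging, point-in-region."""

import math
import random

import pytest
from shapely.geometry import Point, Polygon

from medna import errors
from medna.regions import (
    EARTH_RADIUS_M,
    RegionPolygon,
    RegionSet,
    _equirect_project,
    _point_segment_distance,
    assign_region,
    merge_region_sets,
    read_region_set,
    region_set_from_geojson,
    region_set_to_geojson,
    simplify_douglas_peucker,
    write_region_set,
)
from medna.synth import toy_region_set


def max_deviation_m(original, simplified):
    """Brute force: greatest distance from any input vertex to the output polyline."""
    proj_all = _equirect_project(list(original) + list(simplified))
    proj_orig = proj_all[: len(original)]
    proj_simp = proj_all[len(original):]
    worst = 0.0
    for p in proj_orig:
        best = min(
            _point_segment_distance(p, a, b) for a, b in zip(proj_simp, proj_simp[1:])
        )
        worst = max(worst, best)
    return worst


def random_polyline(rng, n=50):
    lon, lat = rng.uniform(-70, -69), rng.uniform(43, 44)
    pts = [(lon, lat)]
    for _ in range(n - 1):
        lon += rng.uniform(-0.01, 0.02)
        lat += rng.uniform(-0.01, 0.02)
        pts.append((lon, lat))
    return pts


def test_collinear_points_collapse_to_endpoints():
    line = [(0.0, 0.0), (0.5, 0.0), (1.0, 0.0)]
    assert simplify_douglas_peucker(line, 1.0) == [(0.0, 0.0), (1.0, 0.0)]


def test_zero_tolerance_returns_input_unchanged():
    line = [(0.0, 0.0), (0.5, 0.3), (1.0, 0.0)]
    assert simplify_douglas_peucker(line, 0.0) == line


def test_negative_tolerance_rejected():
    with pytest.raises(errors.GeometryError):
        simplify_douglas_peucker([(0, 0), (1, 1)], -1)


def test_deviation_bound_holds_on_random_polylines():
    """Every removed vertex stays within tolerance of the simplified polyline."""
    rng = random.Random(11)
    for _ in range(100):
        line = random_polyline(rng)
        for tol in (10.0, 100.0, 1000.0):
            simp = simplify_douglas_peucker(line, tol)
            assert simp[0] == line[0] and simp[-1] == line[-1]
            # subsequence property
            it = iter(line)
            assert all(v in it for v in simp)
            assert max_deviation_m(line, simp) <= tol + 1e-9


def test_simplification_idempotent_and_tolerance_monotone():
    rng = random.Random(5)
    for _ in range(20):
        line = random_polyline(rng)
        counts = []
        for tol in (10.0, 100.0, 1000.0):
            simp = simplify_douglas_peucker(line, tol)
            assert simplify_douglas_peucker(simp, tol) == simp
            counts.append(len(simp))
        assert counts == sorted(counts, reverse=True)


def test_agrees_with_shapely_on_planar_inputs():
    """Cross-check against shapely's Douglas-Peucker at an equivalent tolerance."""
    rng = random.Random(3)
    # build the polyline at latitude 0 so degrees convert uniformly to metres
    line = [(x * 0.01, rng.uniform(0, 0.01)) for x in range(30)]
    deg_per_m = 180.0 / (math.pi * EARTH_RADIUS_M)
    from shapely.geometry import LineString

    for tol_m in (100.0, 1000.0):
        ours = simplify_douglas_peucker(line, tol_m)
        theirs = list(
            LineString(line).simplify(tol_m * deg_per_m, preserve_topology=False).coords
        )
        assert len(ours) == len(theirs)
        for (ax, ay), (bx, by) in zip(ours, theirs):
            assert math.isclose(ax, bx, abs_tol=1e-9) and math.isclose(ay, by, abs_tol=1e-9)


def test_merge_union_collision_and_bit_exactness():
    toy = toy_region_set()
    watersheds = RegionSet([p for p in toy.polygons() if p.kind == "watershed"])
    marine = RegionSet([p for p in toy.polygons() if p.kind == "marine"])
    merged = merge_region_sets(watersheds, marine)
    assert len(merged) == len(watersheds) + len(marine)
    for code in merged.codes:
        assert merged.get(code).rings == toy.get(code).rings
    colliding = RegionSet([RegionPolygon("GOM", "dup", "watershed", marine.get("GOM").rings)])
    with pytest.raises(errors.MergeError, match="GOM"):
        merge_region_sets(colliding, marine)


def test_legacy_codes_are_two_characters_everything_else_three():
    for poly in toy_region_set().polygons():
        assert len(poly.code) == (2 if poly.legacy else 3)
    with pytest.raises(errors.ValidationError):
        RegionPolygon("ABC", "x", "watershed", [[(0, 0), (1, 0), (1, 1), (0, 0)]], legacy=True)
    with pytest.raises(errors.ValidationError):
        RegionPolygon("AB", "x", "watershed", [[(0, 0), (1, 0), (1, 1), (0, 0)]], legacy=False)


def test_assign_region_containment_and_unassigned():
    square = RegionPolygon(
        "AAA", "unit", "watershed", [[(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]]
    )
    rs = RegionSet([square])
    assert assign_region((0.5, 0.5), rs) == "AAA"
    assert assign_region((0.0, 0.5), rs) == "AAA"  # boundary counts as inside
    with pytest.raises(errors.UnassignedRegionError):
        assign_region((2.0, 2.0), rs)


def shoelace(ring):
    return 0.5 * abs(
        sum(x1 * y2 - x2 * y1 for (x1, y1), (x2, y2) in zip(ring, ring[1:]))
    )


def test_shared_edge_tie_breaks_to_smaller_area():
    big = RegionPolygon("BBB", "big", "watershed", [[(0, 0), (2, 0), (2, 2), (0, 2), (0, 0)]])
    small = RegionPolygon("AAA", "small", "watershed", [[(2, 0), (3, 0), (3, 1), (2, 1), (2, 0)]])
    assert shoelace(small.rings[0]) < shoelace(big.rings[0])
    rs = RegionSet([big, small])
    # the point lies on the shared edge x = 2
    assert assign_region((2.0, 0.5), rs) == "AAA"
    # watershed outranks marine regardless of area
    marine = RegionPolygon("MMM", "sea", "marine", [[(1, 0), (4, 0), (4, 3), (1, 3), (1, 0)]])
    rs2 = RegionSet([big, small, marine])
    assert assign_region((2.0, 0.5), rs2) == "AAA"


def even_odd_contains(poly: RegionPolygon, lon, lat) -> bool:
    """Independent even-odd ray casting with explicit boundary inclusion."""
    shp = Polygon(poly.rings[0], poly.rings[1:])
    if shp.boundary.distance(Point(lon, lat)) < 1e-12:
        return True
    crossings = 0
    for ring in poly.rings:
        for (x1, y1), (x2, y2) in zip(ring, ring[1:]):
            if (y1 > lat) != (y2 > lat):
                x_cross = x1 + (lat - y1) * (x2 - x1) / (y2 - y1)
                if x_cross > lon:
                    crossings += 1
    return crossings % 2 == 1


def test_assignment_agrees_with_brute_force_scan():
    rng = random.Random(17)
    polys = []
    for i in range(10):
        lon0, lat0 = rng.uniform(-72, -68), rng.uniform(42, 45)
        dlon, dlat = rng.uniform(0.5, 2.0), rng.uniform(0.5, 2.0)
        kind = "watershed" if i % 2 == 0 else "marine"
        ring = [
            (lon0, lat0),
            (lon0 + dlon, lat0),
            (lon0 + dlon, lat0 + dlat),
            (lon0, lat0 + dlat),
            (lon0, lat0),
        ]
        polys.append(RegionPolygon(f"R{i:02d}", f"poly {i}", kind, [ring]))
    rs = RegionSet(polys)
    for _ in range(1000):
        lon, lat = rng.uniform(-72.5, -67.5), rng.uniform(41.5, 45.5)
        hits = [p for p in polys if even_odd_contains(p, lon, lat)]
        if not hits:
            with pytest.raises(errors.UnassignedRegionError):
                assign_region((lon, lat), rs)
        else:
            hits.sort(
                key=lambda p: (
                    0 if p.kind == "watershed" else 1,
                    shoelace(p.rings[0]),
                    p.code,
                )
            )
            assert assign_region((lon, lat), rs) == hits[0].code


def test_geojson_roundtrip(tmp_path):
    toy = toy_region_set()
    path = tmp_path / "regions.geojson"
    write_region_set(toy, path)
    back = read_region_set(path)
    assert back.codes == toy.codes
    for code in toy.codes:
        a, b = toy.get(code), back.get(code)
        assert (a.rings, a.kind, a.legacy, a.name) == (b.rings, b.kind, b.legacy, b.name)
    assert region_set_to_geojson(back) == region_set_to_geojson(toy)


def test_geojson_load_enforces_code_length():
    doc = region_set_to_geojson(toy_region_set())
    me = next(f for f in doc["features"] if f["properties"]["code"] == "ME")
    me["properties"]["legacy"] = False  # "ME" claims non-legacy
    with pytest.raises(errors.ValidationError):
        region_set_from_geojson(doc)
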