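"""Region geometry: simplification, merging and point-to-region assignment.

Site IDs embed a 2–3 character region code derived from watershed boundaries
(inland) merged with marine areas (offshore). This module handles the three
geometric jobs that supports:

* polyline/ring simplification with the Douglas–Peucker algorithm, with the
  tolerance given in metres and measured on a local equirectangular
  projection about the polyline centroid (region polygons are hundreds of
  kilometres across, so a local planar metric at 100 m tolerance is ample);
* merging a watershed region set with a marine region set (codes must not
  collide; watershed polygons win ties at assignment time);
* assigning the region code for a sampling point by planar point-in-polygon
  on (lon, lat), boundary-inclusive, with a deterministic tie-break chain:
  watershed over marine, then smaller polygon area, then lexicographic code.

Region sets are read and written as GeoJSON FeatureCollections whose
features carry ``{code, name, kind, legacy}`` properties.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from shapely.geometry import Point, Polygon

from .errors import GeometryError, MergeError, UnassignedRegionError, ValidationError

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius

Coord = tuple[float, float]  # (longitude, latitude), decimal degrees WGS84


# ---------------------------------------------------------------------------
# Douglas–Peucker


def _equirect_project(vertices: Sequence[Coord]) -> list[tuple[float, float]]:
    """Project lon/lat to local metres about the vertex centroid."""
    lat0 = math.radians(sum(v[1] for v in vertices) / len(vertices))
    k = EARTH_RADIUS_M * math.pi / 180.0
    kx = k * math.cos(lat0)
    return [(lon * kx, lat * k) for lon, lat in vertices]


def _point_segment_distance(p, a, b) -> float:
    ax, ay = a
    bx, by = b
    px, py = p
    dx, dy = bx - ax, by - ay
    seg2 = dx * dx + dy * dy
    if seg2 == 0.0:
        return math.hypot(px - ax, py - ay)
    t = ((px - ax) * dx + (py - ay) * dy) / seg2
    t = max(0.0, min(1.0, t))
    return math.hypot(px - (ax + t * dx), py - (ay + t * dy))


def simplify_douglas_peucker(vertices: Sequence[Coord], tolerance_m: float) -> list[Coord]:
    """Simplify a polyline, keeping a subsequence of its vertices.

    The first and last vertices are always retained. Every removed vertex
    lies within ``tolerance_m`` (point-to-segment distance in the local
    metric) of the simplified polyline. ``tolerance_m == 0`` returns the
    input unchanged.
    """
    if tolerance_m < 0:
        raise GeometryError(f"tolerance must be >= 0, got {tolerance_m}")
    verts = [(float(lon), float(lat)) for lon, lat in vertices]
    if len(verts) < 2:
        raise GeometryError("polyline needs at least 2 vertices")
    if tolerance_m == 0 or len(verts) == 2:
        return verts
    proj = _equirect_project(verts)
    keep = [False] * len(verts)
    keep[0] = keep[-1] = True
    stack = [(0, len(verts) - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        a, b = proj[i], proj[j]
        max_d, max_k = -1.0, -1
        for k in range(i + 1, j):
            d = _point_segment_distance(proj[k], a, b)
            if d > max_d:
                max_d, max_k = d, k
        if max_d > tolerance_m:
            keep[max_k] = True
            stack.append((i, max_k))
            stack.append((max_k, j))
    return [v for v, k in zip(verts, keep) if k]


# ---------------------------------------------------------------------------
# region polygons


@dataclass
class RegionPolygon:
    """One coded region: an exterior ring plus optional holes.

    ``legacy`` marks 2-character (Maine watershed) codes; all other codes
    are 3 characters.
    """

    code: str
    name: str
    kind: str  # "watershed" | "marine"
    rings: list[list[Coord]]  # rings[0] exterior, rest holes; closed (first == last)
    legacy: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("watershed", "marine"):
            raise ValidationError(f"region kind must be watershed or marine, got {self.kind!r}")
        expected_len = 2 if self.legacy else 3
        if len(self.code) != expected_len:
            raise ValidationError(
                f"region code {self.code!r}: legacy={self.legacy} requires "
                f"{expected_len} characters"
            )
        if not self.rings:
            raise GeometryError(f"region {self.code}: no rings")
        for ring in self.rings:
            if len(ring) < 4:
                raise GeometryError(f"region {self.code}: ring has fewer than 4 vertices")
            if tuple(ring[0]) != tuple(ring[-1]):
                raise GeometryError(f"region {self.code}: ring is not closed")
            for lon, lat in ring:
                if abs(lat) > 90 or abs(lon) > 180:
                    raise GeometryError(
                        f"region {self.code}: coordinate ({lon}, {lat}) out of range"
                    )

    def shapely(self) -> Polygon:
        return Polygon(self.rings[0], self.rings[1:])

    @property
    def area(self) -> float:
        """Planar polygon area in square degrees (tie-break metric)."""
        return self.shapely().area

    def contains_point(self, lon: float, lat: float) -> bool:
        """Boundary-inclusive planar containment."""
        return self.shapely().covers(Point(lon, lat))

    def simplified(self, tolerance_m: float) -> "RegionPolygon":
        rings = []
        for ring in self.rings:
            simp = simplify_douglas_peucker(ring, tolerance_m)
            # a ring degenerate after simplification keeps its original shape
            rings.append(simp if len(simp) >= 4 else list(ring))
        return RegionPolygon(self.code, self.name, self.kind, rings, self.legacy)


class RegionSet:
    """Collection of region polygons with unique codes."""

    def __init__(self, polygons: Sequence[RegionPolygon] = ()) -> None:
        self._by_code: dict[str, RegionPolygon] = {}
        for poly in polygons:
            self.add(poly)

    def add(self, poly: RegionPolygon) -> None:
        if poly.code in self._by_code:
            raise MergeError(f"duplicate region code {poly.code!r}")
        self._by_code[poly.code] = poly

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def get(self, code: str) -> RegionPolygon:
        return self._by_code[code]

    @property
    def codes(self) -> list[str]:
        return sorted(self._by_code)

    def polygons(self) -> list[RegionPolygon]:
        return [self._by_code[c] for c in self.codes]

    def simplified(self, tolerance_m: float) -> "RegionSet":
        return RegionSet([p.simplified(tolerance_m) for p in self.polygons()])


def merge_region_sets(watersheds: RegionSet, marine: RegionSet) -> RegionSet:
    """Union the two sets; any code collision aborts the merge."""
    collisions = sorted(set(watersheds.codes) & set(marine.codes))
    if collisions:
        raise MergeError(f"region code collision(s): {', '.join(collisions)}")
    return RegionSet(watersheds.polygons() + marine.polygons())


def assign_region(point: Coord, regions: RegionSet) -> str:
    """Region code for a sampling point.

    Boundary points count as inside. When several polygons contain the
    point the winner is chosen by: watershed before marine, then smaller
    planar area, then lexicographically smaller code.
    """
    lon, lat = point
    if abs(lat) > 90 or abs(lon) > 180:
        raise GeometryError(f"point ({lon}, {lat}) out of range")
    hits = [p for p in regions.polygons() if p.contains_point(lon, lat)]
    if not hits:
        raise UnassignedRegionError(
            f"point ({lon}, {lat}) lies in no region; record the survey against an "
            "'other' site instead"
        )
    hits.sort(key=lambda p: (0 if p.kind == "watershed" else 1, p.area, p.code))
    return hits[0].code


# ---------------------------------------------------------------------------
# GeoJSON I/O


def region_set_to_geojson(regions: RegionSet) -> dict:
    features = []
    for poly in regions.polygons():
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(c) for c in ring] for ring in poly.rings],
                },
                "properties": {
                    "code": poly.code,
                    "name": poly.name,
                    "kind": poly.kind,
                    "legacy": poly.legacy,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def region_set_from_geojson(doc: dict) -> RegionSet:
    if doc.get("type") != "FeatureCollection":
        raise ValidationError("region file must be a GeoJSON FeatureCollection")
    regions = RegionSet()
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValidationError(
                f"feature {feat.get('properties', {}).get('code')!r}: only Polygon "
                "geometries are supported"
            )
        props = feat.get("properties") or {}
        for key in ("code", "name", "kind"):
            if key not in props:
                raise ValidationError(f"feature missing required property {key!r}")
        rings = [[(float(lon), float(lat)) for lon, lat in ring] for ring in geom["coordinates"]]
        regions.add(
            RegionPolygon(
                code=str(props["code"]),
                name=str(props["name"]),
                kind=str(props["kind"]),
                rings=rings,
                legacy=bool(props.get("legacy", False)),
            )
        )
    return regions


def write_region_set(regions: RegionSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(region_set_to_geojson(regions), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_region_set(path: str | Path) -> RegionSet:
    return region_set_from_geojson(json.loads(Path(path).read_text(encoding="utf-8")))
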