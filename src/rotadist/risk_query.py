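"""Planning queries against a risk map.

A grower considering candidate coordinates gets the local picture: the risk
map clipped to a circular window around the point, the risk class at the
point itself (boundary ties resolved toward higher risk — conservative
planning advice), and bearing/distance to every previous-year source site
whose outermost buffer reaches the point, so directions of risk are visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from shapely.geometry import Point

from .risk_map import RiskMap, RiskZone, scheme_for_crop
from .vector_io import Layer

__all__ = ["RiskSource", "QueryResult", "query", "bearing_deg", "DEFAULT_RADIUS_MARGIN_M"]

#: Added to the outermost scheme distance for the default clip radius.
DEFAULT_RADIUS_MARGIN_M = 500.0


@dataclass(frozen=True)
class RiskSource:
    """A previous-year site contributing risk at the queried point."""

    id: str
    distance_m: float
    bearing_deg: float


@dataclass
class QueryResult:
    point: tuple[float, float]
    radius_m: float
    local_map: RiskMap
    class_at_point: float | None
    sources: list[RiskSource]

    def summary(self) -> dict:
        return {
            "point": list(self.point),
            "radius_m": self.radius_m,
            "class_at_point": self.class_at_point,
            "sources": [
                {"id": s.id, "distance_m": s.distance_m, "bearing_deg": s.bearing_deg}
                for s in self.sources
            ],
        }


def bearing_deg(from_xy: tuple[float, float], to_xy: tuple[float, float]) -> float:
    """Bearing in degrees clockwise from north (planar coordinates)."""
    dx = to_xy[0] - from_xy[0]
    dy = to_xy[1] - from_xy[1]
    return math.degrees(math.atan2(dx, dy)) % 360.0


def query(
    risk_map: RiskMap,
    previous: Layer,
    point: tuple[float, float],
    radius_m: float | None = None,
    quad_segs: int = 32,
) -> QueryResult:
    """Clip a circular window from the risk map around candidate coordinates.

    ``radius_m`` defaults to the outermost scheme distance plus a 500 m
    margin. Sources are previous-year sites whose outermost buffer (per
    their crop's scheme) covers the point, reported with edge distance and
    bearing to their centroid.
    """
    if not risk_map.zones:
        raise ValueError("risk map is empty")
    x, y = point
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"query point must be finite, got {point}")
    if radius_m is None:
        radius_m = risk_map.scheme.outermost_m + DEFAULT_RADIUS_MARGIN_M
    if radius_m <= 0:
        raise ValueError(f"radius_m must be positive, got {radius_m}")

    pt = Point(x, y)
    disc = pt.buffer(radius_m, quad_segs=quad_segs)
    local_zones = []
    for zone in risk_map.zones:
        clipped = zone.geometry.intersection(disc)
        if not clipped.is_empty and clipped.area > 0:
            local_zones.append(replace(zone, geometry=clipped))
    local_map = RiskMap(
        zones=local_zones,
        scheme=risk_map.scheme,
        source_year=risk_map.source_year,
        crs_id=risk_map.crs_id,
    )

    sources = []
    for site in previous.sites:
        # green-pea sites reach only their own short band; other crops use
        # the map's scheme (which may be a custom override)
        if site.crop == "green_pea":
            reach = scheme_for_crop(site.crop).outermost_m
        else:
            reach = risk_map.scheme.outermost_m
        d = site.geometry.distance(pt)
        if d <= reach:
            c = site.geometry.centroid
            sources.append(
                RiskSource(
                    id=site.id,
                    distance_m=float(d),
                    bearing_deg=bearing_deg((x, y), (c.x, c.y)),
                )
            )
    sources.sort(key=lambda s: s.distance_m)

    return QueryResult(
        point=(x, y),
        radius_m=float(radius_m),
        local_map=local_map,
        class_at_point=risk_map.class_at(x, y),
        sources=sources,
    )
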