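"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's overlay/flattening code path: risk
classes are derived pointwise from exact per-source distances, and nearest
distances from densified boundary vertex pairs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import Point

from rotadist.risk_map import RiskScheme, scheme_for_crop
from rotadist.vector_io import Layer


def sagitta_fraction(quad_segs: int) -> float:
    """Max relative radial shortfall of a chordal circle approximation."""
    return 1.0 - math.cos(math.pi / (4 * quad_segs))


def pointwise_class(
    point: tuple[float, float],
    previous: Layer,
    scheme: RiskScheme,
    mode: str = "one-step",
    quad_segs: int = 16,
):
    """Risk class at a point from per-source distance banding + escalation.

    Returns ``(risk_class_or_None, ambiguous)``. A probe is flagged
    ambiguous when it lies within the chordal sagitta shell of any band
    circle, where a polygon buffer may legitimately disagree with the exact
    distance.
    """
    sag = sagitta_fraction(quad_segs)
    pt = Point(point)
    covering: list[tuple[float, str]] = []
    for site in previous.sites:
        sch = scheme_for_crop(site.crop) if site.crop == "green_pea" else scheme
        d = site.geometry.distance(pt)
        band = None
        for i, dist in enumerate(sch.distances_m):
            if abs(d - dist) <= dist * sag + 1e-9:
                return None, True
            if d <= dist:
                band = i
                break
        if band is not None:
            covering.append((sch.classes[band], site.id))
    if not covering:
        return None, False
    cmax = max(c for c, _ in covering)
    sources = {s for _, s in covering}
    if len(sources) >= 2:
        steps = 1 if mode == "one-step" else len(sources) - 1
        return scheme.next_class(cmax, steps), False
    return cmax, False


def brute_force_boundary_distance(geom_a, geom_b, max_seg: float = 0.4) -> float:
    """Min distance over densified boundary vertex pairs (0 if intersecting)."""
    if geom_a.intersects(geom_b):
        return 0.0
    pa = np.asarray(geom_a.boundary.segmentize(max_seg).coords if geom_a.geom_type == "Polygon"
                    else [c for g in geom_a.geoms for c in g.exterior.segmentize(max_seg).coords])
    pb = np.asarray(geom_b.boundary.segmentize(max_seg).coords if geom_b.geom_type == "Polygon"
                    else [c for g in geom_b.geoms for c in g.exterior.segmentize(max_seg).coords])
    return float(cdist(pa, pb).min())
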