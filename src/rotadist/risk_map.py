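"""Concentric risk buffers, risk classes, and overlap escalation.

Previous-year crop polygons are surrounded by concentric distance bands
(ring buffers). Each band carries a risk class from an ordered ladder
(linear 1,2,3,... or exponential 1,2,4,8,...), decreasing outward. Where
buffers of two or more distinct source fields overlap, infestation pressure
comes from several directions, so the overlap region is escalated to the
next-highest ladder class (saturating at the ladder maximum). The result is
a flat risk map: classed polygons with pairwise disjoint interiors covering
exactly the union of all raw buffers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import polygonize, unary_union
from shapely.strtree import STRtree

from .decay_model import GREEN_PEA_BUFFER_M
from .vector_io import CROP_GRAIN_PEA, CROP_GREEN_PEA, FieldSite, Layer

__all__ = [
    "RiskScheme",
    "RiskZone",
    "RiskMap",
    "nearest_distance",
    "build_buffers",
    "flatten_with_escalation",
    "build_risk_map",
    "grain_pea_scheme",
    "green_pea_scheme",
    "scheme_for_crop",
    "DEFAULT_LADDER",
    "QUAD_SEGS",
]

#: Exponential risk-class ladder used by the default pea-moth schemes.
DEFAULT_LADDER = (1, 2, 4, 8)

#: Segments per quarter circle used to approximate buffer arcs. The maximum
#: radial shortfall of the chordal approximation at radius r is
#: r * (1 - cos(pi / (4 * QUAD_SEGS))).
QUAD_SEGS = 16

EscalationMode = Literal["one-step", "per-source-step"]


@dataclass(frozen=True)
class RiskScheme:
    """Buffer distances paired with risk classes and an escalation ladder.

    ``distances_m`` increase strictly outward while ``classes`` decrease;
    every class is a member of ``ladder``, whose order defines what "next
    highest class" means during overlap escalation. ``cap`` (default: ladder
    maximum) saturates escalation.
    """

    distances_m: tuple[float, ...]
    classes: tuple[float, ...]
    ladder: tuple[float, ...] = DEFAULT_LADDER
    cap: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "distances_m", tuple(float(d) for d in self.distances_m))
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "ladder", tuple(sorted(self.ladder)))
        if self.cap is None:
            object.__setattr__(self, "cap", max(self.ladder))
        if len(self.distances_m) != len(self.classes) or not self.distances_m:
            raise ValueError("distances_m and classes must be equally long and non-empty")
        if any(d2 <= d1 for d1, d2 in zip(self.distances_m, self.distances_m[1:])):
            raise ValueError(f"buffer distances must strictly increase: {self.distances_m}")
        if any(d <= 0 for d in self.distances_m):
            raise ValueError("buffer distances must be positive")
        if any(c2 >= c1 for c1, c2 in zip(self.classes, self.classes[1:])):
            raise ValueError(f"risk classes must strictly decrease outward: {self.classes}")
        missing = [c for c in self.classes if c not in self.ladder]
        if missing:
            raise ValueError(f"classes {missing} are not members of the ladder {self.ladder}")
        if self.cap != max(self.ladder):
            raise ValueError("cap must equal the ladder maximum")

    @property
    def outermost_m(self) -> float:
        return self.distances_m[-1]

    def next_class(self, current: float, steps: int = 1) -> float:
        """Class ``steps`` rungs above ``current`` on the ladder, capped."""
        if current not in self.ladder:
            raise ValueError(f"class {current} is not on the ladder {self.ladder}")
        idx = min(self.ladder.index(current) + steps, len(self.ladder) - 1)
        return min(self.ladder[idx], self.cap)

    @classmethod
    def from_config(cls, cfg: dict) -> "RiskScheme":
        return cls(
            distances_m=tuple(cfg["distances_m"]),
            classes=tuple(cfg["classes"]),
            ladder=tuple(cfg.get("ladder", DEFAULT_LADDER)),
            cap=cfg.get("cap"),
        )

    def to_config(self) -> dict:
        return {
            "distances_m": list(self.distances_m),
            "classes": list(self.classes),
            "ladder": list(self.ladder),
            "cap": self.cap,
        }


def scheme_from_distances(
    distances: Sequence[float],
    classes: Sequence[float] = (4, 2, 1),
    ladder: Sequence[float] = DEFAULT_LADDER,
) -> RiskScheme:
    """Scheme from possibly tied derived distances.

    Fitted buffer distances can coincide (e.g. middle == outer when the two
    fits collapse onto each other); tied bands are merged, keeping the
    higher-risk class of each run.
    """
    uniq: list[float] = []
    cls: list[float] = []
    for d, c in zip(distances, classes):
        if not uniq or d > uniq[-1]:
            uniq.append(d)
            cls.append(c)
    return RiskScheme(distances_m=tuple(uniq), classes=tuple(cls), ladder=tuple(ladder))


def grain_pea_scheme() -> RiskScheme:
    """Default grain-pea scheme: 1261/1560/1825 m bands, classes 4/2/1.

    The distances are the derived pea-moth rotation buffers (decay scale b,
    b + SE, and b + SE of the insecticide-free fit).
    """
    return RiskScheme(distances_m=(1261, 1560, 1825), classes=(4, 2, 1))


def green_pea_scheme() -> RiskScheme:
    """Default green-pea scheme: a single 500 m safety band."""
    return RiskScheme(distances_m=(GREEN_PEA_BUFFER_M,), classes=(4,))


def scheme_for_crop(crop: str) -> RiskScheme:
    if crop == CROP_GREEN_PEA:
        return green_pea_scheme()
    return grain_pea_scheme()


@dataclass
class RiskZone:
    """One classed polygon of a risk map.

    ``band_m`` is the buffer distance band the zone originated from;
    ``source_id`` tracks provenance before flattening (None afterwards for
    merged zones); ``escalated`` marks overlap-escalated regions.
    """

    geometry: BaseGeometry
    risk_class: float
    band_m: float
    escalated: bool = False
    source_id: str | None = None


@dataclass
class RiskMap:
    """Flat set of risk zones with the scheme that produced them."""

    zones: list[RiskZone]
    scheme: RiskScheme
    source_year: int | None = None
    crs_id: str = "unspecified"

    @property
    def union(self) -> BaseGeometry:
        return unary_union([z.geometry for z in self.zones])

    def class_at(self, x: float, y: float) -> float | None:
        """Risk class at a point; boundary ties resolve to the higher class."""
        pt = Point(x, y)
        covering = [z.risk_class for z in self.zones if z.geometry.covers(pt)]
        return max(covering) if covering else None


def nearest_distance(site: FieldSite, previous: Layer) -> float:
    """Edge-to-edge distance to the nearest previous-year site, in meters.

    Zero if the geometries touch or overlap; only the nearest previous site
    matters.
    """
    if not previous.sites:
        raise ValueError("previous-year layer is empty")
    return min(site.geometry.distance(prev.geometry) for prev in previous.sites)


def build_buffers(
    previous: Layer,
    scheme: RiskScheme | None = None,
    quad_segs: int = QUAD_SEGS,
    per_crop: bool = False,
) -> list[RiskZone]:
    """Per-source, possibly overlapping ring buffers around previous sites.

    Band 0 is the full buffer at the innermost distance and includes the
    source polygon itself (a non-rotated field is the maximal-risk case);
    band i > 0 is buffer(d_i) minus buffer(d_{i-1}). With ``per_crop`` the
    scheme is chosen per feature from its crop attribute and ``scheme``
    serves only as the grain-pea override.
    """
    if not previous.sites:
        raise ValueError("previous-year layer is empty")
    zones: list[RiskZone] = []
    for site in previous.sites:
        site_scheme = scheme_for_crop(site.crop) if per_crop else (scheme or grain_pea_scheme())
        if per_crop and scheme is not None and site.crop != CROP_GREEN_PEA:
            site_scheme = scheme
        buffered = [site.geometry.buffer(d, quad_segs=quad_segs) for d in site_scheme.distances_m]
        for i, (dist, cls) in enumerate(zip(site_scheme.distances_m, site_scheme.classes)):
            geom = buffered[i] if i == 0 else buffered[i].difference(buffered[i - 1])
            if geom.is_empty:
                continue
            zones.append(
                RiskZone(geometry=geom, risk_class=cls, band_m=dist, source_id=site.id)
            )
    return zones


def _escalation_steps(n_sources: int, mode: EscalationMode) -> int:
    if n_sources < 2:
        return 0
    return 1 if mode == "one-step" else n_sources - 1


def flatten_with_escalation(
    zones: Sequence[RiskZone],
    scheme: RiskScheme,
    mode: EscalationMode = "one-step",
    source_year: int | None = None,
    crs_id: str = "unspecified",
) -> RiskMap:
    """Overlay per-source buffers into a flat, escalated risk map.

    The union of all zone boundaries is noded and polygonized into atomic
    faces; each face is classified from the zones covering its
    representative point. Faces covered by two or more distinct sources are
    escalated from the maximum covering class — one ladder step by default,
    or one step per additional source with ``mode='per-source-step'`` —
    saturating at the ladder cap. Faces are then dissolved by
    (class, band, escalated).

    The output partitions the union of the inputs: interiors are pairwise
    disjoint and no area is lost.
    """
    if not zones:
        raise ValueError("no zones to flatten")
    boundaries = unary_union([z.geometry.boundary for z in zones])
    faces = list(polygonize(boundaries))
    geoms = [z.geometry for z in zones]
    tree = STRtree(geoms)

    grouped: dict[tuple[float, float, bool], list[Polygon]] = {}
    for face in faces:
        probe = face.representative_point()
        covering = [
            zones[i] for i in tree.query(probe, predicate="intersects")
            if geoms[i].contains(probe)
        ]
        if not covering:
            continue  # face lies in a hole of the arrangement, outside all buffers
        top = max(covering, key=lambda z: (z.risk_class, -z.band_m))
        sources = {z.source_id for z in covering}
        steps = _escalation_steps(len(sources), mode)
        if steps > 0:
            cls = scheme.next_class(top.risk_class, steps)
            escalated = cls != top.risk_class
        else:
            cls, escalated = top.risk_class, False
        grouped.setdefault((cls, top.band_m, escalated), []).append(face)

    out: list[RiskZone] = []
    for (cls, band, escalated), parts in sorted(grouped.items(), reverse=True):
        geom = unary_union(parts)
        out.append(RiskZone(geometry=geom, risk_class=cls, band_m=band, escalated=escalated))
    return RiskMap(zones=out, scheme=scheme, source_year=source_year, crs_id=crs_id)


def build_risk_map(
    previous: Layer,
    scheme: RiskScheme | None = None,
    mode: EscalationMode = "one-step",
    quad_segs: int = QUAD_SEGS,
    per_crop: bool = True,
) -> RiskMap:
    """Buffer + flatten convenience over a previous-year layer.

    Mixed landscapes take the per-feature crop attribute: grain-pea sites get
    the (possibly overridden) grain scheme, green-pea sites the single 500 m
    band. Escalation uses the grain scheme's ladder.
    """
    base = scheme or grain_pea_scheme()
    zones = build_buffers(previous, scheme=base, quad_segs=quad_segs, per_crop=per_crop)
    years = {s.year for s in previous.sites}
    year = max(years) if years else None
    return flatten_with_escalation(
        zones, base, mode=mode, source_year=year, crs_id=previous.crs_id
    )
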