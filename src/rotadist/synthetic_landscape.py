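"""Reproducible synthetic field landscapes and infestation observations.

No public parcel data ship with the package, so testing and demonstration
run on generated landscapes that emulate the study inputs: irregular
convex-ish field parcels of roughly 1-50 ha scattered over a region about
30 km across, one cohort per calendar year, non-overlapping within a year
but freely overlapping across years (so some current fields land right next
to — or on top of — previous-year fields, exercising every distance band).

Observations are drawn from the decay curve itself: for each current field,
the edge-to-edge distance to the nearest previous-year field is computed and
percent infestation simulated as a * exp(-md/b) plus additive Gaussian noise
truncated to the [0, 100] percent domain. Defaults use the published
grain-pea parameters (a = 9.79 %, b = 1260.7 m) and a noise standard
deviation of 9.1 %, the residual scale of the published fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.affinity import rotate, scale, translate
from shapely.geometry import MultiPoint, Polygon

from .decay_model import DistanceObservation
from .risk_map import nearest_distance
from .vector_io import CROP_GRAIN_PEA, FieldSite, Layer

__all__ = ["LandscapeSpec", "generate_fields", "generate_observations", "PackingError"]


class PackingError(RuntimeError):
    """Could not place the requested fields without same-year overlap."""


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of the synthetic landscape and observation generator.

    All randomness is driven by ``seed``; two calls with equal specs produce
    identical output.
    """

    n_fields: int = 30
    region_diameter_m: float = 30_000.0
    area_range_ha: tuple[float, float] = (1.0, 50.0)
    years: tuple[int, ...] = (2015, 2016)
    seed: int = 0
    decay_a: float = 9.79
    decay_b: float = 1260.7
    noise_sd: float = 9.1
    crop: str = CROP_GRAIN_PEA
    crs_id: str = "EPSG:25832"

    def __post_init__(self):
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        if self.region_diameter_m <= 0:
            raise ValueError("region_diameter_m must be positive")
        lo, hi = self.area_range_ha
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid area range {self.area_range_ha}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _random_parcel(rng: np.random.Generator, area_m2: float) -> Polygon:
    """A randomly rotated rectangle perturbed to a convex quadrilateral,
    rescaled to hit the target area exactly."""
    aspect = rng.uniform(1.0, 3.0)
    w = math.sqrt(area_m2 * aspect)
    h = area_m2 / w
    corners = [(-w / 2, -h / 2), (w / 2, -h / 2), (w / 2, h / 2), (-w / 2, h / 2)]
    jitter = 0.12 * min(w, h)
    pts = [(x + rng.uniform(-jitter, jitter), y + rng.uniform(-jitter, jitter)) for x, y in corners]
    poly = MultiPoint(pts).convex_hull
    if not isinstance(poly, Polygon):  # degenerate collinear jitter; fall back
        poly = Polygon(corners)
    poly = rotate(poly, rng.uniform(0, 180), origin="centroid")
    f = math.sqrt(area_m2 / poly.area)
    return scale(poly, xfact=f, yfact=f, origin="centroid")


def generate_fields(spec: LandscapeSpec) -> Layer:
    """Generate the full multi-year layer of synthetic field parcels.

    For each year in ``spec.years``, ``spec.n_fields`` parcels are placed by
    rejection sampling: centers uniform over the circular region, overlap
    with an already-placed same-year parcel triggers a retry (up to 200
    attempts per field, then :class:`PackingError`).
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 0])
    radius = spec.region_diameter_m / 2.0
    lo_m2, hi_m2 = (a * 10_000.0 for a in spec.area_range_ha)
    sites: list[FieldSite] = []
    for year in spec.years:
        placed: list[Polygon] = []
        for i in range(spec.n_fields):
            for _attempt in range(200):
                area = rng.uniform(lo_m2, hi_m2)
                parcel = _random_parcel(rng, area)
                r = radius * math.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * math.pi)
                cx, cy = r * math.cos(theta), r * math.sin(theta)
                c = parcel.centroid
                parcel = translate(parcel, cx - c.x, cy - c.y)
                if all(not parcel.intersects(p) for p in placed):
                    placed.append(parcel)
                    sites.append(
                        FieldSite(
                            id=f"{year}_{i:03d}",
                            geometry=parcel,
                            year=int(year),
                            crop=spec.crop,
                        )
                    )
                    break
            else:
                raise PackingError(
                    f"could not place field {i} of year {year} after 200 attempts; "
                    "reduce n_fields or area range"
                )
    layer = Layer(sites=sites, crs_id=spec.crs_id)
    layer.validate()
    return layer


def generate_observations(
    current: Layer, previous: Layer, spec: LandscapeSpec
) -> list[DistanceObservation]:
    """Simulate infestation observations for current fields.

    For each current field: md = edge-to-edge distance to the nearest
    previous-year field; infestation = decay_a * exp(-md / decay_b) plus
    Normal(0, noise_sd) noise, clipped to [0, 100] percent. Deterministic
    given ``spec.seed`` (an independent stream from field placement).
    """
    if not previous.sites:
        raise ValueError("previous-year layer is empty")
    rng = np.random.default_rng([int(spec.seed) % (2**31), 1])
    obs: list[DistanceObservation] = []
    for site in current.sites:
        md = nearest_distance(site, previous)
        y = spec.decay_a * math.exp(-md / spec.decay_b)
        if spec.noise_sd > 0:
            y += rng.normal(0.0, spec.noise_sd)
        y = min(max(y, 0.0), 100.0)
        obs.append(
            DistanceObservation(md_m=float(md), infestation_pct=float(y), insecticide=site.insecticide)
        )
    return obs


def split_by_year(layer: Layer, year: int) -> Layer:
    """Sub-layer of one cohort year."""
    return Layer(sites=[s for s in layer.sites if s.year == year], crs_id=layer.crs_id)
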