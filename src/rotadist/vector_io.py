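"""Vector layer I/O for field-site polygons and risk maps.

Supports GeoJSON (RFC 7946) and ESRI Shapefile. All geometries must live in
a projected coordinate reference system with meter units: every distance and
buffer in this package is metric, so degree-unit (geographic) CRSs are
rejected unless explicitly allowed.

The attribute schema is fixed: ``id``, ``year``, ``crop``, ``insecticide``,
``infestation_pct`` on field sites and additionally ``risk_class``,
``band_m``, ``escalated`` on risk-map zones. Unknown attributes pass through
untouched. Shapefile DBF field names are limited to 10 characters; the
mapping used is :data:`SHAPEFILE_FIELD_MAP`.
"""

from __future__ import annotations

import json
import logging
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.geometry.polygon import orient

logger = logging.getLogger(__name__)

#: CRS identifiers known to use degree units (geographic, not projected).
GEOGRAPHIC_CRS_IDS = frozenset(
    {
        "EPSG:4326",
        "EPSG:4258",
        "EPSG:4269",
        "EPSG:4267",
        "EPSG:4230",
        "EPSG:4979",
        "OGC:CRS84",
        "CRS84",
        "WGS84",
        "URN:OGC:DEF:CRS:OGC:1.3:CRS84",
    }
)

#: Canonical attribute names -> DBF (<=10 char) field names.
SHAPEFILE_FIELD_MAP = {
    "id": "ID",
    "year": "YEAR",
    "crop": "CROP",
    "insecticide": "INSECTICID",
    "infestation_pct": "INFEST_PCT",
    "risk_class": "RISK_CLASS",
    "band_m": "BAND_M",
    "escalated": "ESCALATED",
    "buffer_m": "BUFFER_M",
}
_SHAPEFILE_FIELD_MAP_INV = {v: k for k, v in SHAPEFILE_FIELD_MAP.items()}

#: Recognised crop labels; anything else is carried as-is.
CROP_GRAIN_PEA = "grain_pea"
CROP_GREEN_PEA = "green_pea"
CROP_OTHER = "other"


class VectorIOError(ValueError):
    """Raised for malformed layers, geometries, or CRS violations."""


@dataclass
class FieldSite:
    """One crop polygon with its planning-relevant attributes.

    ``geometry`` is a valid simple polygon (optionally with holes) or
    multipolygon in planar meter coordinates. ``infestation_pct``, when
    observed, is percent seed infestation in [0, 100].
    """

    id: str
    geometry: BaseGeometry
    year: int
    crop: str = CROP_OTHER
    insecticide: bool | None = None
    infestation_pct: float | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if not isinstance(self.geometry, (Polygon, MultiPolygon)):
            raise VectorIOError(
                f"feature {self.id!r}: geometry must be Polygon or MultiPolygon, "
                f"got {self.geometry.geom_type}"
            )
        if not self.geometry.is_valid:
            raise VectorIOError(f"feature {self.id!r}: invalid geometry")
        if self.geometry.area <= 0:
            raise VectorIOError(f"feature {self.id!r}: zero-area geometry rejected")
        if not (1000 <= int(self.year) <= 9999):
            raise VectorIOError(f"feature {self.id!r}: year {self.year} is not a 4-digit year")
        if self.infestation_pct is not None and not (0.0 <= self.infestation_pct <= 100.0):
            raise VectorIOError(
                f"feature {self.id!r}: infestation_pct {self.infestation_pct} outside [0, 100]"
            )


@dataclass
class Layer:
    """Ordered collection of :class:`FieldSite` sharing one meter-unit CRS."""

    sites: list[FieldSite]
    crs_id: str = "unspecified"

    def validate(self, allow_geographic: bool = False) -> None:
        if not allow_geographic and self.crs_id.upper() in GEOGRAPHIC_CRS_IDS:
            raise VectorIOError(
                f"CRS {self.crs_id!r} uses degree units; a projected meter-unit CRS "
                "is required (distances and buffers are in meters)"
            )
        for site in self.sites:
            site.validate()

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


def _repair(geom: BaseGeometry, feature_id: str) -> BaseGeometry:
    """Standard zero-distance-buffer fix; reject if still invalid."""
    if geom.is_valid:
        return geom
    fixed = geom.buffer(0)
    if not fixed.is_valid or fixed.is_empty or not isinstance(fixed, (Polygon, MultiPolygon)):
        raise VectorIOError(f"feature {feature_id!r}: invalid geometry could not be repaired")
    logger.warning("feature %r: repaired invalid geometry via zero-distance buffer", feature_id)
    return fixed


def _coerce_bool(value: Any) -> bool | None:
    if value is None or value == "":
        return None
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    s = str(value).strip().upper()
    if s in {"T", "TRUE", "Y", "1"}:
        return True
    if s in {"F", "FALSE", "N", "0"}:
        return False
    return None


def _site_from_properties(
    geom: BaseGeometry, props: dict[str, Any], fallback_id: str
) -> FieldSite:
    props = dict(props)
    fid = str(props.pop("id", fallback_id))
    year = int(props.pop("year"))
    crop = str(props.pop("crop", CROP_OTHER))
    insecticide = _coerce_bool(props.pop("insecticide", None))
    inf = props.pop("infestation_pct", None)
    infestation = None if inf is None or inf == "" else float(inf)
    return FieldSite(
        id=fid,
        geometry=geom,
        year=year,
        crop=crop,
        insecticide=insecticide,
        infestation_pct=infestation,
        extra=props,
    )


def _site_properties(site: FieldSite) -> dict[str, Any]:
    props: dict[str, Any] = {"id": site.id, "year": site.year, "crop": site.crop}
    if site.insecticide is not None:
        props["insecticide"] = site.insecticide
    if site.infestation_pct is not None:
        props["infestation_pct"] = site.infestation_pct
    props.update(site.extra)
    return props


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".geojson", ".json"}:
        return "geojson"
    if suffix == ".shp":
        return "shapefile"
    raise VectorIOError(f"cannot infer format from {path.name!r}; pass format explicitly")


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def _read_geojson(path: Path, crs: str | None) -> Layer:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise VectorIOError(f"{path}: expected a GeoJSON FeatureCollection")
    crs_id = crs
    if crs_id is None:
        named = doc.get("crs", {}).get("properties", {}).get("name") if "crs" in doc else None
        crs_id = named or "unspecified"
    sites = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        fid = str(props.get("id", feat.get("id", f"feature_{i}")))
        geom = _repair(shape(feat["geometry"]), fid)
        sites.append(_site_from_properties(geom, props, fid))
    return Layer(sites=sites, crs_id=crs_id)


def _write_geojson(layer: Layer, path: Path) -> None:
    features = []
    for site in layer.sites:
        features.append(
            {
                "type": "Feature",
                "properties": _site_properties(site),
                "geometry": mapping(site.geometry),
            }
        )
    doc: dict[str, Any] = {"type": "FeatureCollection", "features": features}
    if layer.crs_id and layer.crs_id != "unspecified":
        doc["crs"] = {"type": "name", "properties": {"name": layer.crs_id}}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# ESRI Shapefile (polygon type 5) — minimal reader/writer
# ---------------------------------------------------------------------------
# The main file (.shp) holds geometry, the index (.shx) record offsets, and
# the dBASE table (.dbf) the attributes. Exterior rings are written
# clockwise, holes counter-clockwise, per the ESRI white paper.


def _rings_of(geom: Polygon | MultiPolygon) -> list[list[tuple[float, float]]]:
    rings: list[list[tuple[float, float]]] = []
    polys = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    for poly in polys:
        oriented = orient(poly, sign=-1.0)  # CW exterior, CCW holes
        rings.append(list(oriented.exterior.coords))
        for hole in oriented.interiors:
            rings.append(list(hole.coords))
    return rings


def _is_clockwise(ring: Sequence[tuple[float, float]]) -> bool:
    area2 = sum(
        (x2 - x1) * (y2 + y1) for (x1, y1), (x2, y2) in zip(ring[:-1], ring[1:])
    )
    return area2 > 0


def _geometry_from_rings(rings: list[list[tuple[float, float]]]) -> Polygon | MultiPolygon:
    shells = [r for r in rings if _is_clockwise(r)]
    holes = [r for r in rings if not _is_clockwise(r)]
    if not shells:  # degenerate writer produced no CW ring; treat all as shells
        shells, holes = rings, []
    shell_polys = [Polygon(s) for s in shells]
    assigned: list[list[list[tuple[float, float]]]] = [[] for _ in shells]
    for hole in holes:
        probe = Polygon(hole).representative_point()
        for k, sp in enumerate(shell_polys):
            if sp.contains(probe):
                assigned[k].append(hole)
                break
    polys = [Polygon(s, h) for s, h in zip(shells, assigned)]
    return polys[0] if len(polys) == 1 else MultiPolygon(polys)


def _shp_record(geom: Polygon | MultiPolygon) -> bytes:
    rings = _rings_of(geom)
    points = [pt for ring in rings for pt in ring]
    parts = []
    offset = 0
    for ring in rings:
        parts.append(offset)
        offset += len(ring)
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    content = struct.pack("<i", 5)
    content += struct.pack("<4d", min(xs), min(ys), max(xs), max(ys))
    content += struct.pack("<2i", len(parts), len(points))
    content += struct.pack(f"<{len(parts)}i", *parts)
    for x, y in points:
        content += struct.pack("<2d", x, y)
    return content


def _write_shp(layer_geoms: list[Polygon | MultiPolygon], base: Path) -> None:
    records = [_shp_record(g) for g in layer_geoms]
    bounds = [g.bounds for g in layer_geoms]
    xmin = min(b[0] for b in bounds)
    ymin = min(b[1] for b in bounds)
    xmax = max(b[2] for b in bounds)
    ymax = max(b[3] for b in bounds)

    def header(file_words: int) -> bytes:
        hdr = struct.pack(">i5i i", 9994, 0, 0, 0, 0, 0, file_words)
        hdr += struct.pack("<2i", 1000, 5)
        hdr += struct.pack("<8d", xmin, ymin, xmax, ymax, 0.0, 0.0, 0.0, 0.0)
        return hdr

    shp_words = 50 + sum(4 + len(r) // 2 for r in records)
    shx_words = 50 + 4 * len(records)
    with open(base.with_suffix(".shp"), "wb") as shp, open(
        base.with_suffix(".shx"), "wb"
    ) as shx:
        shp.write(header(shp_words))
        shx.write(header(shx_words))
        offset = 50
        for i, rec in enumerate(records, start=1):
            content_words = len(rec) // 2
            shx.write(struct.pack(">2i", offset, content_words))
            shp.write(struct.pack(">2i", i, content_words))
            shp.write(rec)
            offset += 4 + content_words


def _read_shp(path: Path) -> list[Polygon | MultiPolygon]:
    data = path.read_bytes()
    (code,) = struct.unpack(">i", data[0:4])
    if code != 9994:
        raise VectorIOError(f"{path}: not a shapefile (bad file code {code})")
    (shape_type,) = struct.unpack("<i", data[32:36])
    if shape_type != 5:
        raise VectorIOError(f"{path}: only polygon shapefiles are supported (type {shape_type})")
    geoms: list[Polygon | MultiPolygon] = []
    pos = 100
    while pos < len(data):
        (_, content_words) = struct.unpack(">2i", data[pos : pos + 8])
        pos += 8
        rec = data[pos : pos + 2 * content_words]
        pos += 2 * content_words
        (rec_type,) = struct.unpack("<i", rec[0:4])
        if rec_type != 5:
            raise VectorIOError(f"{path}: unsupported record shape type {rec_type}")
        n_parts, n_points = struct.unpack("<2i", rec[36:44])
        parts = list(struct.unpack(f"<{n_parts}i", rec[44 : 44 + 4 * n_parts]))
        pts_off = 44 + 4 * n_parts
        coords = struct.unpack(f"<{2 * n_points}d", rec[pts_off : pts_off + 16 * n_points])
        points = list(zip(coords[0::2], coords[1::2]))
        parts.append(n_points)
        rings = [points[parts[i] : parts[i + 1]] for i in range(n_parts)]
        geoms.append(_geometry_from_rings(rings))
    return geoms


def _dbf_fields(all_props: list[dict[str, Any]]) -> list[tuple[str, str, int, int]]:
    """Derive (name, type, length, decimals) descriptors from property dicts."""
    order: list[str] = []
    for props in all_props:
        for key in props:
            if key not in order:
                order.append(key)
    fields = []
    used_names: set[str] = set()
    for key in order:
        name = SHAPEFILE_FIELD_MAP.get(key, key.upper()[:10])
        while name in used_names:  # avoid truncation collisions
            name = (name[:9] + "X")[:10]
        used_names.add(name)
        values = [p.get(key) for p in all_props]
        non_null = [v for v in values if v is not None]
        if all(isinstance(v, bool) for v in non_null) and non_null:
            fields.append((name, "L", 1, 0))
        elif all(isinstance(v, int) and not isinstance(v, bool) for v in non_null) and non_null:
            width = max(len(str(v)) for v in non_null)
            fields.append((name, "N", max(width, 4), 0))
        elif all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in non_null) and non_null:
            fields.append((name, "N", 19, 6))
        else:
            width = max([len(str(v)) for v in non_null] + [1])
            fields.append((name, "C", min(max(width, 8), 254), 0))
    return fields


def _write_dbf(all_props: list[dict[str, Any]], path: Path) -> None:
    fields = _dbf_fields(all_props)
    record_size = 1 + sum(f[2] for f in fields)
    header_size = 32 + 32 * len(fields) + 1
    buf = bytearray()
    buf += struct.pack("<4B", 0x03, 24, 1, 1)  # version, YMD update stamp
    buf += struct.pack("<I", len(all_props))
    buf += struct.pack("<2H", header_size, record_size)
    buf += bytes(20)
    for name, ftype, length, dec in fields:
        buf += name.encode("ascii").ljust(11, b"\x00")
        buf += ftype.encode("ascii")
        buf += bytes(4)
        buf += struct.pack("<2B", length, dec)
        buf += bytes(14)
    buf += b"\x0d"
    name_to_key = {f[0]: _SHAPEFILE_FIELD_MAP_INV.get(f[0], f[0].lower()) for f in fields}
    for props in all_props:
        buf += b" "
        for name, ftype, length, dec in fields:
            value = props.get(name_to_key[name])
            if ftype == "L":
                cell = b"?" if value is None else (b"T" if value else b"F")
            elif ftype == "N":
                if value is None:
                    cell = b" " * length
                elif dec == 0:
                    cell = str(int(value)).rjust(length).encode("ascii")
                else:
                    cell = f"{float(value):.{dec}f}".rjust(length).encode("ascii")
            else:
                text = "" if value is None else str(value)
                cell = text.encode("utf-8")[:length].ljust(length)
            if len(cell) > length:
                raise VectorIOError(f"DBF field {name}: value {value!r} exceeds width {length}")
            buf += cell
        # record written
    buf += b"\x1a"
    path.write_bytes(bytes(buf))


def _read_dbf(path: Path) -> list[dict[str, Any]]:
    data = path.read_bytes()
    n_records = struct.unpack("<I", data[4:8])[0]
    header_size, record_size = struct.unpack("<2H", data[8:12])
    fields = []
    pos = 32
    while data[pos] != 0x0D:
        raw = data[pos : pos + 32]
        name = raw[0:11].split(b"\x00")[0].decode("ascii")
        ftype = chr(raw[11])
        length, dec = raw[16], raw[17]
        fields.append((name, ftype, length, dec))
        pos += 32
    records = []
    pos = header_size
    for _ in range(n_records):
        rec = data[pos : pos + record_size]
        pos += record_size
        if rec[:1] == b"*":  # deleted
            continue
        props: dict[str, Any] = {}
        off = 1
        for name, ftype, length, dec in fields:
            cell = rec[off : off + length]
            off += length
            key = _SHAPEFILE_FIELD_MAP_INV.get(name, name.lower())
            text = cell.decode("utf-8", errors="replace").strip()
            if ftype == "L":
                props[key] = None if text in {"", "?"} else text in {"T", "Y", "t", "y"}
            elif ftype in {"N", "F"}:
                if not text:
                    props[key] = None
                elif dec == 0 and "." not in text:
                    props[key] = int(text)
                else:
                    props[key] = float(text)
            else:
                props[key] = text
        records.append(props)
    return records


def _read_shapefile(path: Path, crs: str | None) -> Layer:
    geoms = _read_shp(path)
    dbf_path = path.with_suffix(".dbf")
    props = _read_dbf(dbf_path) if dbf_path.exists() else [{} for _ in geoms]
    if len(props) != len(geoms):
        raise VectorIOError(
            f"{path}: attribute table has {len(props)} records for {len(geoms)} shapes"
        )
    sites = []
    for i, (geom, prop) in enumerate(zip(geoms, props)):
        geom = _repair(geom, str(prop.get("id", i)))
        # drop empty-string placeholders written for absent optional attributes
        prop = {k: v for k, v in prop.items() if v != ""}
        sites.append(_site_from_properties(geom, prop, f"feature_{i}"))
    return Layer(sites=sites, crs_id=crs or "unspecified")


def _write_shapefile(layer: Layer, path: Path) -> None:
    base = path.with_suffix("")
    _write_shp([s.geometry for s in layer.sites], base)
    _write_dbf([_site_properties(s) for s in layer.sites], base.with_suffix(".dbf"))
    base.with_suffix(".cpg").write_text("UTF-8", encoding="ascii")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_layer(
    path: str | Path,
    format: str | None = None,
    crs: str | None = None,
    allow_geographic: bool = False,
) -> Layer:
    """Read a polygon layer from GeoJSON or shapefile.

    ``crs`` overrides (GeoJSON) or supplies (shapefile) the CRS identifier;
    shapefiles carry no machine-readable CRS here. Invalid geometries get the
    zero-distance-buffer repair; unrepairable or zero-area features raise
    :class:`VectorIOError` naming the feature id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"layer file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "geojson":
        layer = _read_geojson(path, crs)
    elif fmt == "shapefile":
        layer = _read_shapefile(path, crs)
    else:
        raise VectorIOError(f"unknown format {fmt!r}; use 'geojson' or 'shapefile'")
    layer.validate(allow_geographic=allow_geographic)
    return layer


def write_layer(layer, path: str | Path, format: str | None = None) -> Path:
    """Write a :class:`Layer` or ``RiskMap`` to GeoJSON or shapefile.

    Risk maps are flattened to features whose attributes carry ``risk_class``,
    ``band_m``, ``escalated`` and the source year.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if hasattr(layer, "zones"):  # RiskMap duck-typing avoids an import cycle
        layer = risk_map_to_layer(layer)
    if not layer.sites:
        raise VectorIOError("refusing to write an empty layer")
    layer.validate(allow_geographic=True)
    if fmt == "geojson":
        _write_geojson(layer, path)
    elif fmt == "shapefile":
        _write_shapefile(layer, path)
    else:
        raise VectorIOError(f"unknown format {fmt!r}; use 'geojson' or 'shapefile'")
    return path


def risk_map_to_layer(rmap) -> Layer:
    """Represent a risk map as an attribute-carrying polygon Layer."""
    year = rmap.source_year if rmap.source_year is not None else 9999
    sites = []
    for i, zone in enumerate(rmap.zones):
        sites.append(
            FieldSite(
                id=f"zone_{i:04d}",
                geometry=zone.geometry,
                year=year,
                crop=CROP_OTHER,
                extra={
                    "risk_class": zone.risk_class,
                    "band_m": zone.band_m,
                    "escalated": zone.escalated,
                },
            )
        )
    return Layer(sites=sites, crs_id=rmap.crs_id or "unspecified")
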