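"""Layer I/O, reprojection, and geometry repair.

All file handling lives here so the pipeline core never touches paths.
Formats are detected by extension: ``.geojson``/``.json`` (GeoJSON),
``.shp`` (ESRI Shapefile), ``.gpkg`` (GeoPackage).  GeoJSON files carry the
CRS in the legacy ``crs`` member (written for any non-4326 layer) plus a
``geometry_kind`` foreign member so empty collections round-trip.
"""

from __future__ import annotations

import json
import logging
import math
import re
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from . import _gpkg, _shp, crs as crs_mod
from .errors import CRSError, FormatError
from .layers import LayerSchema, VectorLayer, kind_of

log = logging.getLogger(__name__)

_JSON_EXT = {".geojson", ".json"}


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in _JSON_EXT:
        return "geojson"
    if ext == ".shp":
        return "shapefile"
    if ext == ".gpkg":
        return "geopackage"
    raise FormatError(f"unrecognized vector format {ext!r} for {path}")


def _geojson_crs_to_epsg(doc: dict) -> int:
    member = doc.get("crs")
    if member is None:
        return 4326  # RFC 7946 default
    name = str(member.get("properties", {}).get("name", ""))
    m = re.search(r"EPSG:{1,2}(\d+)", name, flags=re.IGNORECASE)
    if not m:
        raise CRSError(f"cannot parse GeoJSON crs member {name!r}")
    return int(m.group(1))


def _sanitize(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return value


def _records_of(layer: VectorLayer) -> list[dict]:
    return [
        {str(k): _sanitize(v) for k, v in row.items()}
        for row in layer.attributes.to_dict(orient="records")
    ]


def read_layer(path, schema: LayerSchema | None = None) -> VectorLayer:
    """Read a vector layer; optionally validate it against *schema*."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _detect_format(path)
    if fmt == "geojson":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
            feats = doc.get("features", [])
            geometries = [shape(f["geometry"]) for f in feats]
            records = [f.get("properties") or {} for f in feats]
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"unreadable GeoJSON {path}: {exc}") from exc
        epsg = _geojson_crs_to_epsg(doc)
        kind = doc.get("geometry_kind", "")
        if not kind and geometries:
            kind = kind_of(geometries[0])
        layer = VectorLayer.from_records(geometries, records, epsg, kind or "polygon")
    elif fmt == "shapefile":
        geometries, records, epsg, kind = _shp.read_shapefile(path)
        layer = VectorLayer.from_records(geometries, records, epsg, kind)
    else:
        geometries, records, epsg, kind = _gpkg.read_gpkg(path)
        layer = VectorLayer.from_records(geometries, records, epsg, kind or "polygon")
    if schema is not None:
        schema.validate(layer)
    return layer


def write_layer(layer: VectorLayer, path) -> None:
    """Write a layer; an empty layer yields a valid empty collection."""
    path = Path(path)
    if not path.parent.exists():
        raise FormatError(f"parent directory does not exist: {path.parent}")
    fmt = _detect_format(path)
    records = _records_of(layer)
    if fmt == "geojson":
        doc = {
            "type": "FeatureCollection",
            "geometry_kind": layer.geometry_kind,
            "features": [
                {"type": "Feature", "geometry": mapping(g), "properties": rec}
                for g, rec in zip(layer.geometries, records)
            ],
        }
        if layer.crs != 4326:
            doc["crs"] = {
                "type": "name",
                "properties": {"name": f"urn:ogc:def:crs:EPSG::{layer.crs}"},
            }
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    elif fmt == "shapefile":
        _shp.write_shapefile(
            path, layer.geometries, records, layer.crs, layer.geometry_kind
        )
    else:
        _gpkg.write_gpkg(
            path, layer.geometries, records, layer.crs, layer.geometry_kind
        )


def reproject(layer: VectorLayer, target_crs: int) -> VectorLayer:
    """Transform all geometries to *target_crs*; attributes unchanged."""
    target_crs = int(target_crs)
    crs_mod.get_crs(layer.crs)
    crs_mod.get_crs(target_crs)
    if target_crs == layer.crs:
        return layer.copy()

    def _tx(coords: np.ndarray) -> np.ndarray:
        return crs_mod.transform_coords(coords, layer.crs, target_crs)

    geoms = [shapely.transform(g, _tx) for g in layer.geometries]
    return VectorLayer(
        geoms, layer.attributes.copy(), target_crs, layer.geometry_kind
    )


def repair(layer: VectorLayer) -> tuple[VectorLayer, int]:
    """Make every geometry OGC-valid; returns (layer, dropped_count).

    Unrepairable or dimensionally degenerate geometries (e.g. zero-area
    polygons) are dropped and counted.
    """
    keep_idx: list[int] = []
    fixed: list = []
    dropped = 0
    for i, geom in enumerate(layer.geometries):
        g = geom if geom.is_valid else shapely.make_valid(geom)
        if g.geom_type == "GeometryCollection":
            parts = [p for p in g.geoms if kind_of(p) == layer.geometry_kind]
            g = shapely.union_all(parts) if parts else None
        if g is None or g.is_empty:
            dropped += 1
            continue
        if layer.geometry_kind == "polygon" and g.area <= 0:
            dropped += 1
            continue
        if layer.geometry_kind == "line" and g.length <= 0:
            dropped += 1
            continue
        keep_idx.append(i)
        fixed.append(g)
    if dropped:
        log.warning("repair dropped %d unrepairable/degenerate geometries", dropped)
    return (
        VectorLayer(
            fixed,
            layer.attributes.iloc[keep_idx].reset_index(drop=True),
            layer.crs,
            layer.geometry_kind,
        ),
        dropped,
    )


def make_valid(layer: VectorLayer) -> VectorLayer:
    """Validity-repair a layer (see :func:`repair` for the drop count)."""
    return repair(layer)[0]


def check_common_crs(layers, expected: int | None = None) -> int:
    """Raise CRSError unless all layers share one CRS (optionally *expected*)."""
    crss = {layer.crs for layer in layers}
    if len(crss) > 1:
        raise CRSError(f"layers have mixed CRSs: {sorted(crss)}")
    found = crss.pop()
    if expected is not None and found != int(expected):
        raise CRSError(f"layers are in EPSG:{found}, expected EPSG:{expected}")
    return found
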