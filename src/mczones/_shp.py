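"""Minimal ESRI Shapefile reader/writer (.shp/.shx/.dbf/.prj).

Covers the subset the pipeline exchanges: Point/MultiPoint, PolyLine and
Polygon shapes with 2-D coordinates, plus character/numeric/logical DBF
fields.  Ring orientation follows the shapefile convention (outer rings
clockwise, holes counter-clockwise); holes are assigned to the outer ring
that contains them.  The CRS is carried in a .prj sidecar written as OGC
WKT with a trailing EPSG authority clause.
"""

from __future__ import annotations

import datetime as _dt
import re
import struct
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import (
    LineString,
    MultiLineString,
    MultiPoint,
    MultiPolygon,
    Point,
    Polygon,
)
from shapely.geometry.polygon import orient

from .errors import CRSError, FormatError

SHAPE_NULL = 0
SHAPE_POINT = 1
SHAPE_POLYLINE = 3
SHAPE_POLYGON = 5
SHAPE_MULTIPOINT = 8

_WKT = {
    4326: (
        'GEOGCS["WGS 84",DATUM["WGS_1984",SPHEROID["WGS 84",6378137,'
        '298.257223563]],PRIMEM["Greenwich",0],UNIT["degree",'
        '0.0174532925199433],AUTHORITY["EPSG","4326"]]'
    ),
    4269: (
        'GEOGCS["NAD83",DATUM["North_American_Datum_1983",SPHEROID["GRS 1980",'
        '6378137,298.257222101]],PRIMEM["Greenwich",0],UNIT["degree",'
        '0.0174532925199433],AUTHORITY["EPSG","4269"]]'
    ),
    2264: (
        'PROJCS["NAD83 / North Carolina (ftUS)",GEOGCS["NAD83",'
        'DATUM["North_American_Datum_1983",SPHEROID["GRS 1980",6378137,'
        '298.257222101]],PRIMEM["Greenwich",0],UNIT["degree",'
        '0.0174532925199433]],PROJECTION["Lambert_Conformal_Conic_2SP"],'
        'PARAMETER["latitude_of_origin",33.75],PARAMETER["central_meridian",-79],'
        'PARAMETER["standard_parallel_1",34.3333333333333],'
        'PARAMETER["standard_parallel_2",36.1666666666667],'
        'PARAMETER["false_easting",2000000],PARAMETER["false_northing",0],'
        'UNIT["US survey foot",0.304800609601219],AUTHORITY["EPSG","2264"]]'
    ),
    32119: (
        'PROJCS["NAD83 / North Carolina",GEOGCS["NAD83",'
        'DATUM["North_American_Datum_1983",SPHEROID["GRS 1980",6378137,'
        '298.257222101]],PRIMEM["Greenwich",0],UNIT["degree",'
        '0.0174532925199433]],PROJECTION["Lambert_Conformal_Conic_2SP"],'
        'PARAMETER["latitude_of_origin",33.75],PARAMETER["central_meridian",-79],'
        'PARAMETER["standard_parallel_1",34.3333333333333],'
        'PARAMETER["standard_parallel_2",36.1666666666667],'
        'PARAMETER["false_easting",609601.22],PARAMETER["false_northing",0],'
        'UNIT["metre",1],AUTHORITY["EPSG","32119"]]'
    ),
}


def wkt_for_epsg(epsg: int) -> str:
    try:
        return _WKT[int(epsg)]
    except KeyError:
        raise CRSError(f"no WKT registered for EPSG:{epsg}") from None


def epsg_from_wkt(wkt: str) -> int:
    matches = re.findall(r'AUTHORITY\["EPSG",\s*"?(\d+)"?\]', wkt)
    if matches:
        return int(matches[-1])
    low = wkt.lower()
    if "north_carolina" in low or "north carolina" in low:
        return 2264 if ("foot" in low or "ft" in low) else 32119
    if "nad83" in low or "north_american" in low:
        return 4269
    if "wgs" in low:
        return 4326
    raise CRSError("could not determine EPSG code from .prj contents")


# ---------------------------------------------------------------------------
# geometry <-> shp records


def _rings_of(poly: Polygon) -> list[np.ndarray]:
    p = orient(poly, sign=-1.0)  # exterior CW, holes CCW
    rings = [np.asarray(p.exterior.coords, dtype=float)]
    rings += [np.asarray(r.coords, dtype=float) for r in p.interiors]
    return rings


def _encode_shape(geom) -> bytes:
    if geom is None or geom.is_empty:
        return struct.pack("<i", SHAPE_NULL)
    gt = geom.geom_type
    if gt == "Point":
        return struct.pack("<idd", SHAPE_POINT, geom.x, geom.y)
    if gt == "MultiPoint":
        pts = np.asarray([(p.x, p.y) for p in geom.geoms], dtype=float)
        minx, miny = pts.min(axis=0)
        maxx, maxy = pts.max(axis=0)
        return (
            struct.pack("<i4di", SHAPE_MULTIPOINT, minx, miny, maxx, maxy, len(pts))
            + pts.tobytes()
        )
    if gt in ("LineString", "MultiLineString", "Polygon", "MultiPolygon"):
        if gt in ("LineString", "MultiLineString"):
            shape_type = SHAPE_POLYLINE
            parts = (
                [np.asarray(geom.coords, dtype=float)]
                if gt == "LineString"
                else [np.asarray(g.coords, dtype=float) for g in geom.geoms]
            )
        else:
            shape_type = SHAPE_POLYGON
            polys = [geom] if gt == "Polygon" else list(geom.geoms)
            parts = [r for p in polys for r in _rings_of(p)]
        pts = np.vstack(parts)
        minx, miny = pts.min(axis=0)
        maxx, maxy = pts.max(axis=0)
        offsets, off = [], 0
        for part in parts:
            offsets.append(off)
            off += len(part)
        buf = struct.pack(
            "<i4dii", shape_type, minx, miny, maxx, maxy, len(parts), len(pts)
        )
        buf += struct.pack(f"<{len(parts)}i", *offsets)
        buf += pts.tobytes()
        return buf
    raise FormatError(f"cannot write {gt} to shapefile")


def _ring_signed_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def _assemble_polygon(rings: list[np.ndarray]):
    outers = [r for r in rings if _ring_signed_area(r) <= 0]  # CW
    holes = [r for r in rings if _ring_signed_area(r) > 0]
    if not outers:  # malformed writer: treat everything as outer
        outers, holes = rings, []
    shells = [Polygon(r) for r in outers]
    assigned: list[list[np.ndarray]] = [[] for _ in shells]
    for h in holes:
        probe = Point(*h[0])
        for i, s in enumerate(shells):
            if s.contains(probe) or s.touches(probe):
                assigned[i].append(h)
                break
    polys = [Polygon(outers[i], assigned[i]) for i in range(len(shells))]
    return polys[0] if len(polys) == 1 else MultiPolygon(polys)


def _decode_shape(buf: bytes, empty_kind_type: int):
    (shape_type,) = struct.unpack_from("<i", buf, 0)
    if shape_type == SHAPE_NULL:
        return {
            SHAPE_POINT: Point(),
            SHAPE_MULTIPOINT: MultiPoint(),
            SHAPE_POLYLINE: LineString(),
            SHAPE_POLYGON: Polygon(),
        }[empty_kind_type]
    if shape_type == SHAPE_POINT:
        x, y = struct.unpack_from("<dd", buf, 4)
        return Point(x, y)
    if shape_type == SHAPE_MULTIPOINT:
        (n,) = struct.unpack_from("<i", buf, 36)
        pts = np.frombuffer(buf, dtype="<f8", count=2 * n, offset=40).reshape(n, 2)
        return MultiPoint(pts)
    if shape_type in (SHAPE_POLYLINE, SHAPE_POLYGON):
        nparts, npoints = struct.unpack_from("<ii", buf, 36)
        offs = list(struct.unpack_from(f"<{nparts}i", buf, 44)) + [npoints]
        pts = np.frombuffer(
            buf, dtype="<f8", count=2 * npoints, offset=44 + 4 * nparts
        ).reshape(npoints, 2)
        parts = [pts[offs[i] : offs[i + 1]].copy() for i in range(nparts)]
        if shape_type == SHAPE_POLYLINE:
            lines = [LineString(p) for p in parts if len(p) >= 2]
            if not lines:
                return LineString()
            return lines[0] if len(lines) == 1 else MultiLineString(lines)
        rings = [p for p in parts if len(p) >= 4]
        return _assemble_polygon(rings) if rings else Polygon()
    raise FormatError(f"unsupported shapefile shape type {shape_type}")


# ---------------------------------------------------------------------------
# DBF


def _dbf_fields(records: list[dict]) -> list[tuple[str, str, int, int]]:
    names: list[str] = []
    for rec in records:
        for k in rec:
            if k not in names:
                names.append(k)
    fields = []
    for name in names:
        values = [rec.get(name) for rec in records]
        non_null = [v for v in values if v is not None]
        if all(isinstance(v, bool) for v in non_null) and non_null:
            fields.append((name, "L", 1, 0))
        elif all(isinstance(v, (int, np.integer)) for v in non_null) and non_null:
            fields.append((name, "N", 18, 0))
        elif all(
            isinstance(v, (int, float, np.integer, np.floating)) for v in non_null
        ) and non_null:
            fields.append((name, "N", 33, 15))
        else:
            width = max([len(str(v)) for v in non_null] + [1])
            fields.append((name, "C", min(width, 254), 0))
    return fields


def _write_dbf(path: Path, records: list[dict]) -> None:
    fields = _dbf_fields(records)
    record_size = 1 + sum(w for _, _, w, _ in fields)
    header_size = 32 + 32 * len(fields) + 1
    now = _dt.date(2000, 1, 1)  # fixed date keeps outputs byte-reproducible
    with open(path, "wb") as fh:
        fh.write(
            struct.pack(
                "<B3BIHH20x",
                0x03,
                now.year - 1900,
                now.month,
                now.day,
                len(records),
                header_size,
                record_size,
            )
        )
        for name, ftype, width, dec in fields:
            fh.write(
                struct.pack(
                    "<11sc4xBB14x",
                    name[:10].encode("ascii", "replace"),
                    ftype.encode(),
                    width,
                    dec,
                )
            )
        fh.write(b"\x0d")
        for rec in records:
            fh.write(b" ")
            for name, ftype, width, dec in fields:
                v = rec.get(name)
                if ftype == "L":
                    txt = "?" if v is None else ("T" if v else "F")
                elif ftype == "N":
                    if v is None:
                        txt = " " * width
                    elif dec == 0:
                        txt = f"{int(v):>{width}d}"
                    else:
                        txt = f"{float(v):>{width}.{dec}f}"
                else:
                    txt = "" if v is None else str(v)
                    txt = txt[:width].ljust(width)
                raw = txt.encode("utf-8", "replace")
                raw = raw[:width].rjust(width) if ftype == "N" else raw.ljust(width)
                fh.write(raw[:width])
        fh.write(b"\x1a")


def _read_dbf(path: Path) -> list[dict]:
    data = path.read_bytes()
    nrec, header_size, record_size = struct.unpack_from("<IHH", data, 4)
    fields = []
    pos = 32
    while data[pos] != 0x0D:
        raw_name, ftype, width, dec = struct.unpack_from("<11sc4xBB14x", data, pos)
        fields.append((raw_name.split(b"\x00")[0].decode("ascii"), ftype.decode(), width, dec))
        pos += 32
    records = []
    pos = header_size
    for _ in range(nrec):
        if pos >= len(data) or data[pos : pos + 1] == b"\x1a":
            break
        deleted = data[pos : pos + 1] == b"*"
        off = pos + 1
        rec = {}
        for name, ftype, width, dec in fields:
            raw = data[off : off + width]
            off += width
            txt = raw.decode("utf-8", "replace").strip()
            if ftype == "N":
                if not txt:
                    rec[name] = None
                elif dec == 0 and "." not in txt:
                    rec[name] = int(txt)
                else:
                    rec[name] = float(txt)
            elif ftype == "L":
                rec[name] = None if txt in ("", "?") else txt in "TtYy"
            else:
                rec[name] = txt
        pos += record_size
        if not deleted:
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# public entry points


def write_shapefile(path, geometries, records, epsg, geometry_kind) -> None:
    path = Path(path)
    kind_type = {
        "point": SHAPE_POINT,
        "line": SHAPE_POLYLINE,
        "polygon": SHAPE_POLYGON,
    }[geometry_kind]
    non_empty = [g for g in geometries if g is not None and not g.is_empty]
    if geometry_kind == "point" and any(
        g.geom_type == "MultiPoint" for g in non_empty
    ):
        if any(g.geom_type == "Point" for g in non_empty):
            raise FormatError("shapefile cannot mix Point and MultiPoint features")
        kind_type = SHAPE_MULTIPOINT

    shapes = [_encode_shape(g) for g in geometries]
    if non_empty:
        bounds = shapely.total_bounds(non_empty)
    else:
        bounds = np.zeros(4)
    content_words = sum((8 + len(s)) // 2 for s in shapes)
    header = struct.pack(
        ">i5ii", 9994, 0, 0, 0, 0, 0, 50 + content_words
    ) + struct.pack("<ii4d4d", 1000, kind_type, *bounds, 0, 0, 0, 0)

    with open(path, "wb") as fh, open(path.with_suffix(".shx"), "wb") as fx:
        fh.write(header)
        fx.write(
            struct.pack(">i5ii", 9994, 0, 0, 0, 0, 0, 50 + 4 * len(shapes))
            + struct.pack("<ii4d4d", 1000, kind_type, *bounds, 0, 0, 0, 0)
        )
        offset_words = 50
        for i, s in enumerate(shapes, start=1):
            fh.write(struct.pack(">ii", i, len(s) // 2))
            fh.write(s)
            fx.write(struct.pack(">ii", offset_words, len(s) // 2))
            offset_words += 4 + len(s) // 2

    recs = records if records else [{} for _ in shapes]
    _write_dbf(path.with_suffix(".dbf"), recs)
    path.with_suffix(".prj").write_text(wkt_for_epsg(epsg), encoding="ascii")


def read_shapefile(path):
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 100 or struct.unpack_from(">i", data, 0)[0] != 9994:
        raise FormatError(f"{path} is not a shapefile")
    (file_type,) = struct.unpack_from("<i", data, 32)
    geometries = []
    pos = 100
    while pos + 8 <= len(data):
        _, content_words = struct.unpack_from(">ii", data, pos)
        pos += 8
        geometries.append(_decode_shape(data[pos : pos + 2 * content_words], file_type))
        pos += 2 * content_words

    dbf = path.with_suffix(".dbf")
    records = _read_dbf(dbf) if dbf.exists() else [{} for _ in geometries]

    prj = path.with_suffix(".prj")
    if not prj.exists():
        raise CRSError(f"{path} has no .prj sidecar; CRS is required")
    epsg = epsg_from_wkt(prj.read_text(encoding="ascii", errors="replace"))

    kind = {
        SHAPE_POINT: "point",
        SHAPE_MULTIPOINT: "point",
        SHAPE_POLYLINE: "line",
        SHAPE_POLYGON: "polygon",
    }.get(file_type)
    if kind is None:
        raise FormatError(f"unsupported shapefile type code {file_type}")
    return geometries, records, epsg, kind
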