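"""Minimal GeoPackage (OGC 12-128r15) feature-table reader/writer.

Writes a single feature table per file with the required metadata tables
(gpkg_spatial_ref_sys, gpkg_contents, gpkg_geometry_columns) and standard
GeoPackage geometry blobs (GP header + ISO WKB, little-endian, no envelope).
Only what the pipeline needs: 2-D geometries and TEXT/INTEGER/REAL columns.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

import numpy as np
import shapely

from . import _shp
from .errors import FormatError

_GPKG_APPLICATION_ID = 0x47504B47  # "GPKG"

_GEOM_NAME = {
    "point": "MULTIPOINT",
    "line": "MULTILINESTRING",
    "polygon": "MULTIPOLYGON",
}


def _geometry_blob(geom, srs_id: int) -> bytes:
    # magic "GP", version 0, flags: little-endian header, no envelope
    flags = 0b00000001 | (0b00010000 if geom.is_empty else 0)
    header = b"GP" + bytes([0, flags]) + int(srs_id).to_bytes(4, "little", signed=True)
    return header + shapely.to_wkb(geom, byte_order=1)


_ENVELOPE_DOUBLES = {0: 0, 1: 4, 2: 6, 3: 6, 4: 8}


def _parse_blob(blob: bytes):
    if blob is None:
        return None
    if blob[:2] != b"GP":
        raise FormatError("not a GeoPackage geometry blob")
    flags = blob[3]
    envelope = (flags >> 1) & 0b111
    n = _ENVELOPE_DOUBLES.get(envelope)
    if n is None:
        raise FormatError(f"invalid GeoPackage envelope indicator {envelope}")
    return shapely.from_wkb(bytes(blob[8 + 8 * n :]))


def _sql_type(values) -> str:
    non_null = [v for v in values if v is not None]
    if non_null and all(isinstance(v, (bool, int, np.integer)) for v in non_null):
        return "INTEGER"
    if non_null and all(
        isinstance(v, (bool, int, float, np.integer, np.floating)) for v in non_null
    ):
        return "REAL"
    return "TEXT"


def write_gpkg(path, geometries, records, epsg, geometry_kind, table="layer") -> None:
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        cur = con.cursor()
        cur.execute(f"PRAGMA application_id = {_GPKG_APPLICATION_ID}")
        cur.execute("PRAGMA user_version = 10300")
        cur.execute(
            """CREATE TABLE gpkg_spatial_ref_sys (
                 srs_name TEXT NOT NULL, srs_id INTEGER PRIMARY KEY,
                 organization TEXT NOT NULL, organization_coordsys_id INTEGER NOT NULL,
                 definition TEXT NOT NULL, description TEXT)"""
        )
        cur.executemany(
            "INSERT INTO gpkg_spatial_ref_sys VALUES (?,?,?,?,?,?)",
            [
                ("Undefined Cartesian", -1, "NONE", -1, "undefined", None),
                ("Undefined geographic", 0, "NONE", 0, "undefined", None),
            ],
        )
        cur.execute(
            "INSERT INTO gpkg_spatial_ref_sys VALUES (?,?,?,?,?,?)",
            (f"EPSG:{epsg}", int(epsg), "EPSG", int(epsg), _shp.wkt_for_epsg(epsg), None),
        )
        cur.execute(
            """CREATE TABLE gpkg_contents (
                 table_name TEXT NOT NULL PRIMARY KEY, data_type TEXT NOT NULL,
                 identifier TEXT UNIQUE, description TEXT DEFAULT '',
                 last_change DATETIME, min_x DOUBLE, min_y DOUBLE,
                 max_x DOUBLE, max_y DOUBLE, srs_id INTEGER)"""
        )
        non_empty = [g for g in geometries if not g.is_empty]
        bounds = shapely.total_bounds(non_empty) if non_empty else [None] * 4
        cur.execute(
            "INSERT INTO gpkg_contents VALUES (?,?,?,?,?,?,?,?,?,?)",
            (
                table,
                "features",
                table,
                "",
                "2000-01-01T00:00:00.000Z",  # fixed: keeps outputs reproducible
                *[None if b is None else float(b) for b in bounds],
                int(epsg),
            ),
        )
        cur.execute(
            """CREATE TABLE gpkg_geometry_columns (
                 table_name TEXT NOT NULL PRIMARY KEY, column_name TEXT NOT NULL,
                 geometry_type_name TEXT NOT NULL, srs_id INTEGER NOT NULL,
                 z TINYINT NOT NULL, m TINYINT NOT NULL)"""
        )
        cur.execute(
            "INSERT INTO gpkg_geometry_columns VALUES (?,?,?,?,?,?)",
            (table, "geom", _GEOM_NAME[geometry_kind], int(epsg), 0, 0),
        )

        recs = records if records else [{} for _ in geometries]
        names: list[str] = []
        for rec in recs:
            for k in rec:
                if k not in names:
                    names.append(k)
        types = {n: _sql_type([r.get(n) for r in recs]) for n in names}
        cols = "".join(f', "{n}" {types[n]}' for n in names)
        cur.execute(
            f'CREATE TABLE "{table}" '
            f"(fid INTEGER PRIMARY KEY AUTOINCREMENT, geom BLOB{cols})"
        )
        placeholders = ",".join(["?"] * (1 + len(names)))
        rows = []
        for geom, rec in zip(geometries, recs):
            vals = []
            for n in names:
                v = rec.get(n)
                if isinstance(v, (np.integer,)):
                    v = int(v)
                elif isinstance(v, (np.floating,)):
                    v = float(v)
                elif isinstance(v, (bool, np.bool_)):
                    v = int(v)
                vals.append(v)
            rows.append((_geometry_blob(geom, epsg), *vals))
        if rows:
            colnames = "geom" + "".join(f', "{n}"' for n in names)
            cur.executemany(
                f'INSERT INTO "{table}" ({colnames}) VALUES ({placeholders})', rows
            )
        con.commit()
    finally:
        con.close()


def read_gpkg(path, table: str | None = None):
    path = Path(path)
    con = sqlite3.connect(path)
    try:
        cur = con.cursor()
        try:
            feats = cur.execute(
                "SELECT table_name, srs_id FROM gpkg_contents "
                "WHERE data_type='features' ORDER BY table_name"
            ).fetchall()
        except sqlite3.DatabaseError as exc:
            raise FormatError(f"{path} is not a GeoPackage: {exc}") from exc
        if not feats:
            raise FormatError(f"{path} contains no feature tables")
        if table is None:
            table, epsg = feats[0]
        else:
            match = [f for f in feats if f[0] == table]
            if not match:
                raise FormatError(f"no feature table {table!r} in {path}")
            table, epsg = match[0]
        geom_col, type_name = cur.execute(
            "SELECT column_name, geometry_type_name FROM gpkg_geometry_columns "
            "WHERE table_name=?",
            (table,),
        ).fetchone()
        info = cur.execute(f'PRAGMA table_info("{table}")').fetchall()
        attr_cols = [r[1] for r in info if r[1] not in ("fid", geom_col)]
        sel = f'"{geom_col}"' + "".join(f', "{c}"' for c in attr_cols)
        geometries, records = [], []
        for row in cur.execute(f'SELECT {sel} FROM "{table}" ORDER BY fid'):
            geometries.append(_parse_blob(row[0]))
            records.append(dict(zip(attr_cols, row[1:])))
        kind = {
            "POINT": "point",
            "MULTIPOINT": "point",
            "LINESTRING": "line",
            "MULTILINESTRING": "line",
            "POLYGON": "polygon",
            "MULTIPOLYGON": "polygon",
        }.get(type_name.upper(), "")
        return geometries, records, int(epsg), kind
    finally:
        con.close()
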