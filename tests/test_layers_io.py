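"""Layer container, file round-trips, schema validation, geometry repair."""

import numpy as np
import pytest
import shapely
from shapely.geometry import (
    LineString,
    MultiPolygon,
    Point,
    Polygon,
    box,
)

import mczones as mz
from mczones.gis_io import repair

FORMATS = ["geojson", "shp", "gpkg"]


def _sample_layers():
    polys = mz.VectorLayer.from_records(
        [box(0, 0, 1, 1), MultiPolygon([box(2, 0, 3, 1), box(4, 0, 5, 1)])],
        [
            {"NAME": "unit square", "VALUE": 3, "RATE": 0.5},
            {"NAME": "two parts", "VALUE": -1, "RATE": 2.25},
        ],
        2264,
        "polygon",
    )
    lines = mz.VectorLayer.from_records(
        [LineString([(0, 0), (10, 0), (10, 10)])], [{"NAME": "bent"}], 2264, "line"
    )
    points = mz.VectorLayer.from_records(
        [Point(1.5, 2.5), Point(-3.25, 7.0)],
        [{"ADDR_ID": 1}, {"ADDR_ID": 2}],
        2264,
        "point",
    )
    return {"polygon": polys, "line": lines, "point": points}


@pytest.mark.parametrize("fmt", FORMATS)
@pytest.mark.parametrize("kind", ["polygon", "line", "point"])
def test_write_read_round_trip(tmp_path, fmt, kind):
    layer = _sample_layers()[kind]
    path = tmp_path / f"layer.{fmt}"
    mz.write_layer(layer, path)
    back = mz.read_layer(path)
    assert back.crs == layer.crs
    assert back.geometry_kind == kind
    assert len(back) == len(layer)
    for a, b in zip(layer.geometries, back.geometries):
        # normalize: ring orientation/start point are format semantics
        # (shapefile mandates clockwise outer rings), not geometry
        assert shapely.equals_exact(
            shapely.normalize(a), shapely.normalize(b), tolerance=1e-9
        )
    for col in layer.attributes.columns:
        want = list(layer.attributes[col])
        got = list(back.column(col))
        if layer.attributes[col].dtype.kind in "if":
            assert got == pytest.approx(want)
        else:
            assert got == want


@pytest.mark.parametrize("fmt", FORMATS)
def test_empty_layer_round_trips(tmp_path, fmt):
    layer = mz.VectorLayer.from_records([], None, 2264, "polygon")
    path = tmp_path / f"empty.{fmt}"
    mz.write_layer(layer, path)
    back = mz.read_layer(path)
    assert len(back) == 0
    assert back.crs == 2264


@pytest.mark.parametrize("fmt", FORMATS)
def test_multipolygon_part_count_preserved(tmp_path, fmt):
    mp = MultiPolygon([box(0, 0, 1, 1), box(2, 2, 3, 3), box(5, 5, 6, 6)])
    layer = mz.VectorLayer.from_records([mp], [{"NAME": "3 parts"}], 2264, "polygon")
    path = tmp_path / f"mp.{fmt}"
    mz.write_layer(layer, path)
    back = mz.read_layer(path)
    assert back.geometries[0].geom_type == "MultiPolygon"
    assert len(back.geometries[0].geoms) == 3


def test_geojson_unit_square_identity(tmp_path):
    path = tmp_path / "sq.geojson"
    path.write_text(
        '{"type":"FeatureCollection","features":[{"type":"Feature",'
        '"geometry":{"type":"Polygon","coordinates":[[[0,0],[1,0],[1,1],[0,1],'
        '[0,0]]]},"properties":{"NAME":"sq"}}]}'
    )
    layer = mz.read_layer(path)
    assert len(layer) == 1
    assert layer.geometry_kind == "polygon"
    assert layer.crs == 4326  # GeoJSON default
    assert layer.geometries[0].area == pytest.approx(1.0)


def test_crs_tag_written(tmp_path):
    layer = _sample_layers()["polygon"]
    path = tmp_path / "crs.geojson"
    mz.write_layer(layer, path)
    assert "2264" in path.read_text()


def test_schema_violation_names_missing_attribute(tmp_path):
    layer = mz.VectorLayer.from_records(
        [box(0, 0, 1, 1)], [{"OWNER_TYPE": "Private"}], 2264, "polygon"
    )
    path = tmp_path / "heritage.geojson"
    mz.write_layer(layer, path)
    with pytest.raises(mz.SchemaError, match="GAP_STATUS"):
        mz.read_layer(path, schema=mz.HERITAGE_SCHEMA)


def test_attribute_lookup_is_case_insensitive():
    layer = mz.VectorLayer.from_records(
        [box(0, 0, 1, 1)], [{"Gap_Status": "1: x", "OWNER_TYPE": "s"}], 2264, "polygon"
    )
    assert list(layer.column("GAP_STATUS")) == ["1: x"]
    mz.HERITAGE_SCHEMA.validate(layer)  # no raise


def test_mixed_geometry_kinds_rejected():
    with pytest.raises(mz.SchemaError, match="mixed"):
        mz.VectorLayer.from_records(
            [box(0, 0, 1, 1), Point(0, 0)], None, 2264
        )


def test_unknown_format_and_missing_file(tmp_path):
    with pytest.raises(mz.FormatError, match="no such file"):
        mz.read_layer(tmp_path / "nothing.geojson")
    layer = _sample_layers()["polygon"]
    with pytest.raises(mz.FormatError):
        mz.write_layer(layer, tmp_path / "layer.xyz")


# --- make_valid -----------------------------------------------------------


def test_make_valid_keeps_valid_square():
    layer = mz.VectorLayer.from_records([box(0, 0, 4, 4)], None, 2264, "polygon")
    out = mz.make_valid(layer)
    assert shapely.equals(out.geometries[0], layer.geometries[0])


def test_make_valid_bowtie_area_matches_shoelace_lobes():
    # self-intersecting quadrilateral; lobes are two triangles of area 4 each
    bowtie = Polygon([(0, 0), (4, 4), (4, 0), (0, 4)])
    assert not bowtie.is_valid

    def shoelace(pts):
        x = np.array([p[0] for p in pts] + [pts[0][0]])
        y = np.array([p[1] for p in pts] + [pts[0][1]])
        return 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))

    lobes = shoelace([(0, 0), (2, 2), (0, 4)]) + shoelace([(4, 0), (4, 4), (2, 2)])
    layer = mz.VectorLayer.from_records([bowtie], None, 2264, "polygon")
    out = mz.make_valid(layer)
    assert out.geometries[0].is_valid
    assert out.geometries[0].area == pytest.approx(lobes, rel=1e-12)


def test_make_valid_drops_degenerate_and_counts():
    degenerate = Polygon([(0, 0), (1, 1), (2, 2), (0, 0)])  # zero area
    layer = mz.VectorLayer.from_records(
        [box(0, 0, 1, 1), degenerate], None, 2264, "polygon"
    )
    out, dropped = repair(layer)
    assert dropped == 1
    assert len(out) == 1


def test_make_valid_is_idempotent():
    bowtie = Polygon([(0, 0), (4, 4), (4, 0), (0, 4)])
    layer = mz.VectorLayer.from_records([bowtie], None, 2264, "polygon")
    once = mz.make_valid(layer)
    twice = mz.make_valid(once)
    assert len(once) == len(twice)
    for a, b in zip(once.geometries, twice.geometries):
        assert shapely.equals(a, b)
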