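"""Reprojection: identity, round-trips, and a frozen ellipsoidal-geodesic check.

The geodesic reference distances below were computed independently with
ellipsoidal geodesics on GRS80 (geosphere::distGeo).  A conformal conic
projection distorts lengths by its scale factor, which is 1 on the standard
parallels and stays within ~1e-4 across the NC State Plane zone, so planar
distances must match geodesics to that order.
"""

import numpy as np
import pytest
import shapely
from shapely.geometry import Point, Polygon, box

import mczones as mz
from mczones import crs as crs_mod

# (lon, lat) pairs and their GRS80 geodesic separation in metres
GEODESIC_CASES = [
    (((-79.0, 34.333333), (-78.5, 34.333333)), 46011.135500, 5e-7),  # on parallel 1
    (((-78.64, 35.78), (-77.95, 34.22)), 184171.859151, 2e-4),
    (((-77.0, 36.1), (-76.8, 36.0)), 21163.404704, 1e-4),
]


def _layer_of_points(pts, epsg):
    return mz.VectorLayer.from_records(
        [Point(p) for p in pts], None, epsg, "point"
    )


@pytest.mark.parametrize("pts,geodesic_m,rtol", GEODESIC_CASES)
def test_projected_distance_matches_ellipsoidal_geodesic(pts, geodesic_m, rtol):
    layer = _layer_of_points(pts, 4269)
    out = mz.reproject(layer, 2264)
    (a, b) = out.geometries
    planar_m = a.distance(b) * crs_mod.US_SURVEY_FOOT_M
    assert planar_m == pytest.approx(geodesic_m, rel=rtol)


def test_reproject_to_own_crs_is_identity():
    layer = _layer_of_points([(2000000.0, 500000.0), (2100000.0, 650000.0)], 2264)
    out = mz.reproject(layer, 2264)
    for a, b in zip(layer.geometries, out.geometries):
        assert shapely.equals_exact(a, b, tolerance=1e-9)


def test_projection_round_trip_preserves_area():
    square = box(2000000.0, 500000.0, 2030000.0, 530000.0)  # ~5.7 mi on a side
    layer = mz.VectorLayer.from_records([square], None, 2264, "polygon")
    back = mz.reproject(mz.reproject(layer, 4269), 2264)
    assert back.geometries[0].area == pytest.approx(square.area, rel=1e-6)


def test_false_origin_maps_to_false_easting():
    out = crs_mod.transform_coords(np.array([[-79.0, 33.75]]), 4269, 2264)
    assert out[0, 0] == pytest.approx(2_000_000.0, abs=1e-6)
    assert out[0, 1] == pytest.approx(0.0, abs=1e-6)


def test_feet_and_metre_state_plane_variants_agree():
    pts = np.array([[-78.2, 34.9], [-77.5, 35.6]])
    ft = crs_mod.transform_coords(pts, 4269, 2264)
    m = crs_mod.transform_coords(pts, 4269, 32119)
    # same LCC, different unit and false easting
    np.testing.assert_allclose(
        (ft[:, 0] - 2_000_000.0) * crs_mod.US_SURVEY_FOOT_M,
        m[:, 0] - 609601.22,
        atol=1e-6,
    )
    np.testing.assert_allclose(
        ft[:, 1] * crs_mod.US_SURVEY_FOOT_M, m[:, 1], atol=1e-6
    )


def test_unknown_epsg_rejected():
    layer = _layer_of_points([(0.0, 0.0)], 4326)
    with pytest.raises(mz.CRSError, match="unknown EPSG"):
        mz.reproject(layer, 999999)


def test_geographic_working_crs_rejected_by_config():
    with pytest.raises(mz.ConfigError, match="geographic"):
        mz.PipelineConfig(county_name="X", working_crs=4326)


def test_mixed_crs_inputs_rejected_before_geometry_work(simple_case):
    layers, _ = simple_case
    layers = {k: v.copy() for k, v in layers.items()}
    layers["wetlands"].crs = 32119
    with pytest.raises(mz.CRSError, match="mixed"):
        mz.run_pipeline(layers, mz.default_config())
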