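"""Property-based invariants for grid indexing and geometry repair."""

from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon

import mczones as mz

coords = st.floats(
    min_value=-50_000.0, max_value=50_000.0, allow_nan=False, allow_infinity=False
)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.tuples(coords, coords), min_size=1, max_size=40))
def test_fishnet_covers_every_address_with_disjoint_lattice_cells(pts):
    cfg = mz.PipelineConfig(county_name="X")
    layer = mz.VectorLayer.from_records(
        [Point(p) for p in pts], None, 2264, "point"
    )
    cells = mz.build_fishnet(layer, cfg)
    ids = [c.cell_id for c in cells]
    assert len(ids) == len(set(ids))  # lattice cells never repeat
    side = cfg.cell_side
    for c in cells:
        minx, miny, maxx, maxy = c.geometry.bounds
        assert (maxx - minx, maxy - miny) == (side, side)
    # every address lies in (or on the boundary of) at least one retained cell
    for p in pts:
        assert any(c.geometry.intersects(Point(p)) for c in cells)
    # every retained cell contains at least one address (default sparse mode)
    for c in cells:
        assert any(c.geometry.intersects(Point(p)) for p in pts)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
            st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
        ),
        min_size=3,
        max_size=8,
    )
)
def test_make_valid_idempotent_and_ogc_valid_on_arbitrary_rings(ring):
    poly = Polygon(ring)
    if poly.is_empty:
        return
    layer = mz.VectorLayer.from_records([poly], None, 2264, "polygon")
    once = mz.make_valid(layer)
    twice = mz.make_valid(once)
    for g in once.geometries:
        assert g.is_valid
    assert len(once) == len(twice)
    for a, b in zip(once.geometries, twice.geometries):
        assert a.equals(b)
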