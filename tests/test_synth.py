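"""Generator determinism, parameter monotonicity, and oracle convergence."""

import numpy as np
import pytest
import shapely

import mczones as mz


def _bundles_equal(a, b) -> bool:
    if set(a) != set(b):
        return False
    for key in a:
        la, lb = a[key], b[key]
        if len(la) != len(lb) or la.crs != lb.crs:
            return False
        if not la.attributes.equals(lb.attributes):
            return False
        for ga, gb in zip(la.geometries, lb.geometries):
            if not shapely.equals_exact(ga, gb, tolerance=0.0):
                return False
    return True


def test_same_seed_gives_identical_bundle():
    params = mz.CountyParams(side=3 * 5280.0, n_addresses=60, seed=42)
    assert _bundles_equal(mz.generate_county(params), mz.generate_county(params))


def test_different_seeds_differ():
    a = mz.generate_county(mz.CountyParams(side=3 * 5280.0, n_addresses=60, seed=1))
    b = mz.generate_county(mz.CountyParams(side=3 * 5280.0, n_addresses=60, seed=2))
    assert not _bundles_equal(a, b)


def test_bundle_layers_live_inside_county():
    params = mz.CountyParams(side=3 * 5280.0, n_addresses=60, seed=7)
    bundle = mz.generate_county(params)
    county = bundle["counties"].geometries[0].buffer(1.0)
    for key in ("waterbodies", "wetlands", "addresses", "blocks"):
        for g in bundle[key].geometries:
            assert county.covers(g), f"{key} feature escapes the county"


def test_wetland_fraction_zero_yields_no_approved_cells():
    params = mz.CountyParams(
        side=3 * 5280.0, n_addresses=60, wetland_fraction=0.0, seed=5
    )
    bundle = mz.generate_county(params)
    _, summary = mz.run_pipeline(bundle, mz.default_config(params))
    assert summary.classes[mz.CLASS_APPROVED].cell_count == 0


def test_wetland_fraction_hits_target_within_two_percent():
    params = mz.CountyParams(side=4 * 5280.0, wetland_fraction=0.4, seed=3)
    bundle = mz.generate_county(params)
    county_area = bundle["counties"].geometries[0].area
    wet = shapely.union_all(bundle["wetlands"].geometries).area
    assert wet == pytest.approx(0.4 * county_area, rel=0.02)


def test_invalid_params_rejected():
    with pytest.raises(mz.GenerationError):
        mz.CountyParams(wetland_fraction=2.0)
    with pytest.raises(mz.GenerationError):
        mz.CountyParams(side=-1.0)
    with pytest.raises(mz.GenerationError):
        mz.CountyParams(address_clustering="ring")


def test_zero_addresses_bundle_valid_but_pipeline_raises_step8():
    params = mz.CountyParams(side=3 * 5280.0, n_addresses=0, seed=9)
    bundle = mz.generate_county(params)
    assert len(bundle["addresses"]) == 0
    with pytest.raises(mz.PipelineError, match="step 8"):
        mz.run_pipeline(bundle, mz.default_config(params))


def test_oracle_approved_fills_grid_when_all_wet_no_sensitive():
    params = mz.CountyParams(
        side=3 * 5280.0,
        n_rivers=0,
        n_lakes=0,
        n_preserves=0,
        wetland_fraction=0.9,
        n_addresses=80,
        seed=13,
    )
    bundle = mz.generate_county(params)
    # replace wetlands with full-county coverage: every retained cell is wet
    bundle["wetlands"] = mz.VectorLayer.from_records(
        bundle["counties"].geometries, [{"WETLAND_ID": 0}], 2264, "polygon"
    )
    cfg = mz.default_config(params)
    ref = mz.raster_oracle(bundle, cfg, 10.0)
    cells = mz.build_fishnet(bundle["addresses"], cfg)
    grid_area = sum(c.geometry.area for c in cells)
    assert ref.areas[mz.CLASS_APPROVED] == pytest.approx(grid_area, rel=0.01)
    assert ref.areas[mz.CLASS_WARNING] == 0.0


def test_oracle_vector_discrepancy_shrinks_with_resolution(small_bundle):
    bundle, cfg, _ = small_bundle
    _, summary = mz.run_pipeline(bundle, cfg)
    vec = {k: t.area_ft2 for k, t in summary.classes.items()}
    discrepancies = []
    for res in (40.0, 20.0, 10.0):
        ref = mz.raster_oracle(bundle, cfg, res)
        d = sum(abs(vec[k] - ref.areas[k]) for k in vec)
        discrepancies.append(d)
    # halving the pixel edge must not inflate the discrepancy by more than 2x
    assert discrepancies[1] <= 2.0 * discrepancies[0] + 1e-9
    assert discrepancies[2] <= 2.0 * discrepancies[1] + 1e-9
    assert discrepancies[2] <= discrepancies[0] + 1e-9


def test_oracle_rejects_too_coarse_resolution(small_bundle):
    bundle, cfg, _ = small_bundle
    with pytest.raises(mz.MczonesError, match="too coarse"):
        mz.raster_oracle(bundle, cfg, 100.0)


def test_oracle_approved_area_monotone_in_wetland_fraction():
    areas = []
    for fraction in (0.1, 0.3, 0.5):
        params = mz.CountyParams(
            side=3 * 5280.0,
            n_rivers=1,
            n_lakes=2,
            n_preserves=1,
            wetland_fraction=fraction,
            n_addresses=60,
            seed=21,
        )
        bundle = mz.generate_county(params)
        ref = mz.raster_oracle(bundle, mz.default_config(params), 20.0)
        areas.append(ref.areas[mz.CLASS_APPROVED])
    assert areas[0] <= areas[1] + 1e-9
    assert areas[1] <= areas[2] + 1e-9
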