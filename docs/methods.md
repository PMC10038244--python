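# Methods

## The classification model

The pipeline classifies a county into spray-planning zones on a square-cell
grid. Its inputs are ordinary county GIS layers; its outputs are a classified
grid, per-class area/population summaries, and a cost projection. The model
rests on three operational assumptions:

1. **No-treatment geometry is a single dissolved region.** Water bodies,
   buffered stream/river corridors (default 50 ft each side of the
   centerline) and protected heritage polygons (GAP status 1–2, i.e. managed
   for biodiversity, or federal ownership) are merged, clipped to the county,
   expanded by a drift buffer (default 100 ft) and dissolved into one
   *sensitive area*. The drift buffer stands in for insecticide droplet
   drift: treatment must stop short of protected land, not merely at its
   boundary.
2. **The grid is indexed to structures, not to the county.** Cells (default
   1 mi², side 5280 ft) are axis-aligned squares anchored to the CRS origin;
   by default only cells containing at least one address point are kept, so
   the grid follows where people actually are. `keep_empty_cells` switches to
   the full bounding block.
3. **Classification is cell-level and exclusive.** After the sensitive area
   is erased from the cells, a cell is Warning if its remaining geometry lies
   within the warning distance (default 100 ft, inclusive) of the sensitive
   area; otherwise Approved if it intersects a wetland (boundary touch
   counts), else Not Significant. Warning takes precedence over Approved: the
   wetness test is applied only to the non-warning remainder, so a wet cell
   near protected land is still flagged.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `hydro_half_width` | 50 | working-CRS unit (ft) | stream/river corridor half-width |
| `sensitive_buffer` | 100 | ft | drift buffer around merged no-treatment polygons |
| `warning_distance` | 100 | ft | cell-to-sensitive-area distance for Warning |
| `cell_area` | 27 878 400 | ft² | grid cell area (1 mi²) |
| `gap_keep_values` | [1, 2] | — | GAP codes kept (leading integer compared) |
| `owner_keep_values` | ["federal land"] | — | owner types kept (case-insensitive) |
| `keep_empty_cells` | false | — | retain address-free cells |
| `apportionment` | area_weighted | — | population split mode |
| `sliver_min_area` | 1 | ft² | post-erase slivers below this are dropped |
| `working_crs` | 2264 | — | projected CRS; degrees rejected |

All lengths/areas are in the working CRS's linear unit. The defaults encode
the protocol's printed values for a feet-based CRS; EPSG:2264 (NC State
Plane, US survey foot) is the default because the protocol's distances are in
feet and its areas in mi². Square-mile and acre conversions use survey feet
(1 mi² = 27 878 400 ft², 1 mi² = 640 acres, acres computed exactly as
mi² × 640).

## Coordinate handling

No projection library is bundled as a dependency; the package implements the
ellipsoidal Lambert Conformal Conic (2SP) forward/inverse mapping on GRS80 /
WGS84 for the four EPSG codes it supports (4326, 4269, 2264, 32119). The
NAD83↔WGS84 datum shift (< 2 m) is treated as identity — three orders of
magnitude below the cell scale. The implementation is verified in the test
suite against frozen ellipsoidal-geodesic distances (computed with an
independent geodesic library): projected planar distances match geodesics to
~5×10⁻⁸ on the standard parallels and within the conic's ~10⁻⁴ scale
distortion elsewhere, and round-trip area error is below 10⁻⁶ relative.

## Numerical choices

* **Buffers** use ≥ 64 arc segments per quarter circle, so closed-form areas
  (round-capped corridor: `2·w·L + π·w²`; rounded rectangle:
  `s² + 4·s·w + π·w²`) hold to 10⁻³ relative.
* **Distance predicate** is inclusive (≤). Cells abutting the erased
  boundary have distance exactly zero; a tie at exactly the warning distance
  is classified Warning.
* **Wetness predicate** is DE-9IM `intersects` (boundary touch counts),
  evaluated between the post-erase cell geometry and the county-clipped (not
  erased) wetlands, since the post-erase geometry is what remains treatable.
* **Merge vs. dissolve**: the step-4 merge is pure concatenation; the union
  happens once, in step 6, which also records the dissolved component count.
* **Robustness**: every layer is validity-repaired before overlay work
  (unrepairable or zero-area geometries are dropped and counted); post-erase
  slivers below 1 ft² are discarded.
* **Rounding**: mi² are reported at 2 decimal places; all internal arithmetic
  is double precision.
* **Determinism**: no stage consults randomness or iteration order of hashed
  containers; repeated runs produce byte-identical exports (fixed timestamps
  are written into DBF/GPKG metadata for this reason).

## Population apportionment

`area_weighted` (default) assigns each cell
`Σ_b pop_b · area(cell ∩ b) / area(b)`. Summed over the grid this equals each
block's population times the fraction of the block the grid covers, which the
tests verify to 10⁻⁶ relative; it avoids double counting when a block spans
several cells. `block_copy` reproduces a plain GIS intersect-join — every
intersecting cell receives the whole block population — and is provided for
comparability, documented as over-counting. Cell `density` is population per
cell area (people/ft² in the default CRS).

## Synthetic counties

The generator emulates the structure of the real layer stack on a square
county (default side 10 mi): smoothed random-walk rivers crossing the county,
elliptical lakes, rectangular preserves whose GAP_STATUS/OWNER_TYPE values
cycle through the real vocabulary (so the heritage filter is exercised by
kept *and* dropped features), wetland blobs rescaled by bisection until their
union hits the target county fraction ± 2 %, clustered or uniform address
points, and an n×n census-block tiling with log-uniform populations in
[10, 1000] (spanning rural to dense blocks). Defaults (4 rivers, 6 lakes,
4 preserves, wetland fraction 0.35, 400 addresses, 8×8 blocks) were chosen
once to resemble a mid-size coastal-plain county with substantial wetland
cover; the seed fully determines the bundle.

What the generator does *not* emulate: real hydrographic network topology,
Census TIGER block shapes, coastline concavity, or attribute noise. Passing
tests therefore demonstrate the correctness of the overlay/classification
machinery under realistic geometric complexity (concave, multi-part,
overlapping features), not calibration to any real county.

## The raster oracle

`raster_oracle` re-derives per-class areas on a pixel raster as an
independent second route through steps 9–17. Pixel centres over the retained
grid extent are labelled by the same rules: membership in the sensitive area
and in wetlands by point-in-region sampling, distance to the sensitive area
by a Euclidean distance transform, aggregated per cell (a cell is Warning if
its treatable region comes within the warning distance; Approved if any
treatable pixel is wet). Pixel-centre sampling is unbiased for area as the
resolution shrinks, and the discrepancy against the vector route is
first-order in the pixel edge — the convergence test checks 40/20/10 ft.

One refinement prevents a quantisation artefact: a cell whose true distance
to the sensitive area falls within about one pixel of the threshold could
have its *entire* area flipped between classes by pixel rounding. For cells
whose estimated distance lies within two pixels of the threshold (and for
wetness near-misses), the oracle re-evaluates the predicate with exact
geometric distance/intersection on that cell alone. The areas being
cross-checked — erase accounting, per-class pixel counts, wetness coverage —
remain independently computed.

Test scale: the seeded-batch invariant suite runs twenty 4-mi counties with
sparser hydrology (2 rivers, 3 lakes, 2 preserves) so the 10-ft oracle stays
fast and all three classes appear across the batch; the acceptance script
uses the full 10-mi default county.

## Design choices where the protocol is open

* **Grid anchoring.** "Grid index features" tools anchor grids in
  tool-specific ways; here the origin snaps the address bounding box down to
  a multiple of the cell side from the CRS origin, making cell boundaries
  independent of feature order and reproducible across runs.
* **Warning measured to the buffered layer.** "Within 100 ft of the
  sensitive area (+100 ft buffer)" is read as distance to the *buffered*
  layer; the alternative (200 ft from the raw layer) differs near concave
  boundaries and is not implemented.
* **Hand fixture at 5×5 cells.** With the preserve exactly filling the centre
  cell, every edge- and corner-adjacent cell touches the erased boundary
  (distance 0), so in a 3×3 county *all* ring cells would be Warning and no
  cell could be Approved or Not Significant. A 5×5 county is the smallest
  square in which the erased cell, its Warning ring, an Approved column and a
  Not Significant remainder all coexist with hand-derivable labels.
* **Single county per run.** Statewide batches are out of scope; the CLI
  takes explicit per-layer paths because source data archive layouts vary.

## Full-scale reproduction

The published per-county results (Brunswick 369.90/212.12 mi² Approved/
Warning, Columbus 640.45/66.21, Onslow 244/194.94, Robeson 682/22) were
produced from NC OneMap extracts that are distributed separately and are
not redistributable inside this repository; the
reproduction test (`tests/test_acceptance.py::test_published_county_areas_reproduce`)
therefore looks for the layers under `data/nc_onemap/<county>/<role>.{geojson,gpkg,shp}`
(roles: counties, heritage, streams, waterbodies, wetlands, addresses,
blocks), reprojects them to EPSG:2264, runs the default-parameter pipeline,
and compares each county's Approved/Warning/total areas at ±1 % — the
documented allowance for geometry-engine differences from the original
implementation. Without the data the test fails with an explanatory message
rather than passing vacuously. Expect roughly 10 minutes per county at full
scale on one CPU.

## Known limitations

* Only the four registered EPSG codes are supported; other projected CRSs
  would need registry entries.
* Shapefile support covers 2-D Point/PolyLine/Polygon with C/N/L DBF fields —
  enough for the pipeline's layer stack, not a general-purpose driver.
* The endangered-species (USFWS) review that follows map production is an
  administrative step and is not modelled.
* `block_copy` apportionment intentionally over-counts; use it only to mimic
  legacy intersect-joins.
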