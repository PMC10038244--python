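# mczones

Classified treatment-zone grids for emergency mosquito control planning.

After hurricane flooding, county health officials need to decide quickly where
aerial or ground insecticide application is justified — and where it must not
happen because protected land, open water, or managed conservation areas would
be hit by spray drift. `mczones` turns a county's standard GIS layers
(county boundary, Natural Heritage / protected-land polygons with GAP_STATUS
and OWNER_TYPE codes, stream and river centerlines, water bodies, wetlands,
address points, and census blocks) into a 1-mi² fishnet grid in which every
cell is classified:

* **Approved** — treatable area intersecting wetlands, the likely mosquito
  habitat;
* **Warning** — treatable area within 100 ft of the buffered biologically
  sensitive area, flagged because drift could reach protected land;
* **Not Significant** — cells with structures but no wetland habitat, not
  worth treating.

The classification follows an 18-step overlay protocol: select the county;
keep heritage polygons managed for biodiversity (GAP status 1–2) or federally
owned; buffer stream centerlines by 50 ft per side; merge with water bodies;
clip to the county; expand everything by a 100-ft drift buffer and dissolve it
into a single *sensitive area*; clip the wetlands; build a square grid
(default 1 mi², anchored to the CRS origin) indexed to the address points;
erase the sensitive area from the grid; classify cells within 100 ft of the
sensitive area as Warning; classify the inverted remainder as Approved (wet)
or Not Significant (dry); merge; and apportion census-block population onto
the cells by overlap area. Per-class areas (mi², acres), cell counts and
populations feed a cost projection over the vetted (Approved + Warning)
acres.

All distances and areas are interpreted in the linear unit of the working CRS
(default EPSG:2264, NC State Plane, US survey feet). The package is
self-contained: it reads and writes GeoJSON, ESRI Shapefile and GeoPackage,
reprojects between the supported EPSG codes (4326/4269 geographic, 2264/32119
NC State Plane) with a built-in Lambert Conformal Conic implementation, and
ships a deterministic synthetic-county generator plus an independent
raster-classification oracle so the whole pipeline is testable without any
data download.

## Worked example

`examples/hand_fixture_walkthrough.py` runs the pipeline on a hand-derivable
5×5-cell county — a preserve filling the centre cell and a wetland strip down
the west column — and prints:

```
grid (row 4 at top; X = erased centre cell):
  A . . . .
  A W W W .
  A W X W .
  A W W W .
  A . . . .

cells matching the hand-derived classes: 24/24
          class  cell_count  area_mi2  area_acres  population
       Approved           5      5.00     3200.00      500.00
        Warning           8      7.92     5070.79      792.31
Not Significant          11     11.00     7040.00     1100.00
          Total          24     23.92    15310.79     2392.31
```

The centre cell disappears (fully erased by the preserve plus its 100-ft
buffer); the eight ring cells touch the erased boundary, so they are Warning
and slightly smaller than 1 mi² (7.92 total); the five west-column cells
intersect the wetland strip and are Approved; population (2500 in one block)
is apportioned by overlap area, so the classified grid carries
2500 × 23.92/25 ≈ 2392 people.

Other examples: `classify_synthetic_county.py` (end-to-end run with cost
projection), `raster_cross_check.py` (vector areas vs. the raster oracle at
40/20/10-ft resolution), `io_and_reprojection.py` (formats and CRS handling).

## Command line

```bash
# classify a county from explicit layer paths
mczones run --county Brunswick \
    --county-layer county.gpkg --heritage-layer nhp.gpkg \
    --streams-layer streams.gpkg --waterbodies-layer water.gpkg \
    --wetlands-layer wetlands.gpkg --addresses-layer addresses.gpkg \
    --blocks-layer blocks.gpkg --out-dir out/ --map

# generate a synthetic county bundle plus raster reference areas
mczones synth --seed 7 --out-dir bundle/
```

`run` writes the classified grid (GeoJSON or GeoPackage), `summary.csv`, an
optional PNG map (Approved green, Warning red; population choropleth white →
dark purple), and a `manifest.json` recording the config, input checksums and
per-step feature counts. Every failure exits non-zero with a single-line,
step-numbered message.

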