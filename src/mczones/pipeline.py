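"""The 18-step treatment-zone protocol.

Converts county vector layers (protected lands, hydrology, wetlands, address
points, census blocks) into a classified 1-mi2 fishnet grid:

* **Approved** — treatable cells intersecting wetlands (likely mosquito
  habitat);
* **Warning** — treatable cells within the warning distance of the buffered
  biologically sensitive area, flagged because insecticide drift could reach
  protected land;
* **Not Significant** — cells with structures but no wetland habitat.

The stages map one-to-one onto the published protocol steps: select county
(1), filter heritage polygons (2), buffer stream centerlines (3), merge
no-treatment polygons (4), clip to the county (5), buffer + dissolve into a
single sensitive area (6), clip wetlands (7), build the address-indexed
fishnet (8), erase the sensitive area (9), classify Warning (10-12), classify
the inverted remainder (13-16), merge classes (17), apportion census-block
population (18).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.strtree import STRtree

from .config import MI2_IN_SQFT, PipelineConfig
from .crs import ACRES_PER_MI2, unit_to_us_feet
from .errors import (
    CRSError,
    EmptyInputError,
    MczonesError,
    PipelineError,
    SchemaError,
)
from .gis_io import check_common_crs, repair
from .layers import VectorLayer

log = logging.getLogger(__name__)

BUFFER_QUAD_SEGS = 64  # >= 64 arc segments per quarter circle
CLASS_WARNING = "Warning"
CLASS_APPROVED = "Approved"
CLASS_NOT_SIGNIFICANT = "Not Significant"
CLASSES = (CLASS_APPROVED, CLASS_WARNING, CLASS_NOT_SIGNIFICANT)

REQUIRED_LAYERS = (
    "counties",
    "heritage",
    "streams",
    "waterbodies",
    "wetlands",
    "addresses",
    "blocks",
)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SensitiveArea:
    """Dissolved, buffered union of all no-treatment geometry (steps 4-6)."""

    geometry: shapely.Geometry
    component_count: int
    area: float
    crs: int

    @property
    def is_empty(self) -> bool:
        return self.geometry.is_empty


@dataclass
class GridCell:
    cell_id: tuple[int, int]  # (row, col)
    geometry: shapely.Geometry
    type: str = "unset"
    population: float = 0.0
    density: float = 0.0

    @property
    def area(self) -> float:
        return self.geometry.area


@dataclass
class ClassifiedGrid:
    cells: list[GridCell]
    crs: int
    config: PipelineConfig

    def __len__(self) -> int:
        return len(self.cells)

    def of_class(self, name: str) -> list[GridCell]:
        return [c for c in self.cells if c.type == name]

    def to_layer(self) -> VectorLayer:
        ft = unit_to_us_feet(self.crs)
        records = []
        for c in self.cells:
            area_ft2 = c.area * ft * ft
            records.append(
                {
                    "cell_row": c.cell_id[0],
                    "cell_col": c.cell_id[1],
                    "Type": c.type,
                    "area_ft2": area_ft2,
                    "area_mi2": area_ft2 / MI2_IN_SQFT,
                    "population": c.population,
                    "density_ppl_ft2": c.density / (ft * ft),
                }
            )
        return VectorLayer.from_records(
            [c.geometry for c in self.cells], records, self.crs, "polygon"
        )


@dataclass
class ClassTotals:
    area_ft2: float = 0.0
    cell_count: int = 0
    population: float = 0.0

    @property
    def area_mi2(self) -> float:
        return self.area_ft2 / MI2_IN_SQFT

    @property
    def area_acres(self) -> float:
        return self.area_mi2 * ACRES_PER_MI2


@dataclass
class ZoneSummary:
    """Per-class areas (mi2 reported at 2 dp), cell counts and populations."""

    classes: dict[str, ClassTotals] = field(default_factory=dict)

    @property
    def total(self) -> ClassTotals:
        return ClassTotals(
            sum(t.area_ft2 for t in self.classes.values()),
            sum(t.cell_count for t in self.classes.values()),
            sum(t.population for t in self.classes.values()),
        )

    @property
    def treatable(self) -> ClassTotals:
        """Approved + Warning: the vetted area for cost projection."""
        rows = [
            self.classes.get(CLASS_APPROVED, ClassTotals()),
            self.classes.get(CLASS_WARNING, ClassTotals()),
        ]
        return ClassTotals(
            sum(t.area_ft2 for t in rows),
            sum(t.cell_count for t in rows),
            sum(t.population for t in rows),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in CLASSES:
            t = self.classes.get(name, ClassTotals())
            rows.append(
                {
                    "class": name,
                    "cell_count": t.cell_count,
                    "area_mi2": round(t.area_mi2, 2),
                    "area_acres": round(t.area_acres, 2),
                    "population": round(t.population, 2),
                }
            )
        t = self.total
        rows.append(
            {
                "class": "Total",
                "cell_count": t.cell_count,
                "area_mi2": round(t.area_mi2, 2),
                "area_acres": round(t.area_acres, 2),
                "population": round(t.population, 2),
            }
        )
        return pd.DataFrame(rows)


@dataclass
class CostReport:
    treatable_acres: float
    cost_per_acre: float
    product_rate: float

    @property
    def total_cost(self) -> float:
        return self.treatable_acres * self.cost_per_acre

    @property
    def product_amount(self) -> float:
        return self.treatable_acres * self.product_rate


# ---------------------------------------------------------------------------
# stage operations


def _polygonal(geom):
    """Keep only the polygonal component of an overlay result."""
    if geom.geom_type == "GeometryCollection":
        parts = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        return shapely.union_all(parts) if parts else shapely.Polygon()
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom
    return shapely.Polygon()


def _find_name_field(layer: VectorLayer, preferred=("county", "name", "county_nam")):
    for want in preferred:
        for col in layer.attributes.columns:
            if want in str(col).lower():
                return col
    raise SchemaError(
        f"no county-name attribute found among {list(layer.attributes.columns)}"
    )


def select_county(
    counties: VectorLayer, name: str, name_field: str | None = None
) -> VectorLayer:
    """Step 1: SQL-style County = name selection, dissolved to one feature."""
    if counties.geometry_kind != "polygon":
        raise SchemaError("county layer must be polygonal")
    col = name_field or _find_name_field(counties)
    values = counties.attributes[col].astype(str).str.strip().str.lower()
    target = str(name).strip().lower()
    mask = values == target
    if not mask.any():
        available = sorted(values.unique())
        raise MczonesError(
            f"county {name!r} not found; available: {available}"
        )
    selected = counties.subset(list(mask))
    geometry = shapely.union_all(selected.geometries)
    return VectorLayer.from_records(
        [geometry], [{col: str(name).strip()}], counties.crs, "polygon"
    )


_LEADING_INT = re.compile(r"^\s*(\d+)")


def _leading_int(value) -> int | None:
    if isinstance(value, (int, np.integer)):
        return int(value)
    m = _LEADING_INT.match(str(value))
    return int(m.group(1)) if m else None


def _strip_code(value: str) -> str:
    return re.sub(r"^\s*\d+\s*:\s*", "", str(value)).strip().lower()


def filter_heritage(heritage: VectorLayer, config: PipelineConfig) -> VectorLayer:
    """Step 2: keep GAP status 1/2 (managed for biodiversity) or federal land.

    GAP matching compares the leading integer of the attribute, so
    ``"1: Managed for biodiversity; ..."`` matches a keep value of ``1``.
    Owner matching is case-insensitive on the text after any ``"n:"`` code
    prefix, with containment either way ("Federal Land" matches
    "federal land").
    """
    if heritage.is_empty:
        return heritage.copy()
    gap = heritage.column("GAP_STATUS")
    owner = heritage.column("OWNER_TYPE")
    gap_keep = {
        v for v in (_leading_int(k) for k in config.gap_keep_values) if v is not None
    }
    owner_keep = [_strip_code(k) for k in config.owner_keep_values]

    def keep(g, o) -> bool:
        if _leading_int(g) in gap_keep:
            return True
        otext = _strip_code(o)
        return any(k and (k in otext or otext in k) for k in owner_keep)

    mask = [keep(g, o) for g, o in zip(gap, owner)]
    return heritage.subset(mask)


def buffer_hydro_lines(lines: VectorLayer, half_width: float) -> VectorLayer:
    """Step 3: widen stream/river centerlines into corridors of 2x half_width."""
    if lines.geometry_kind != "line":
        raise SchemaError(f"expected line layer, got {lines.geometry_kind}")
    if half_width <= 0:
        raise MczonesError("half_width must be > 0")
    keep, geoms, dropped = [], [], 0
    for i, geom in enumerate(lines.geometries):
        if geom.is_empty or geom.length <= 0:
            dropped += 1
            continue
        keep.append(i)
        geoms.append(
            geom.buffer(half_width, quad_segs=BUFFER_QUAD_SEGS)
        )  # round caps/joins by default
    if dropped:
        log.warning("buffer_hydro_lines dropped %d zero-length lines", dropped)
    return VectorLayer(
        geoms,
        lines.attributes.iloc[keep].reset_index(drop=True),
        lines.crs,
        "polygon",
    )


def merge_layers(layers: Sequence[VectorLayer]) -> VectorLayer:
    """Step 4: concatenate polygon layers; attributes reduce to a source tag.

    No dissolve happens here — overlaps survive until step 6.
    """
    non_empty = [lyr for lyr in layers if not lyr.is_empty]
    for lyr in layers:
        if lyr.geometry_kind != "polygon":
            raise SchemaError("merge_layers accepts polygon layers only")
    if not non_empty:
        return VectorLayer.from_records(
            [], None, layers[0].crs if layers else 2264, "polygon"
        )
    crs = check_common_crs(non_empty)
    geoms, tags = [], []
    for i, lyr in enumerate(non_empty):
        geoms.extend(lyr.geometries)
        tags.extend([{"src_layer": i}] * len(lyr))
    return VectorLayer.from_records(geoms, tags, crs, "polygon")


def clip_layer(layer: VectorLayer, boundary: VectorLayer) -> VectorLayer:
    """Steps 5 and 7: cookie-cutter intersection with a single polygon."""
    if len(boundary) != 1 or boundary.geometry_kind != "polygon":
        raise MczonesError("clip boundary must be a single polygon feature")
    check_common_crs([layer, boundary])
    cutter = boundary.geometries[0]
    if cutter.is_empty:
        raise EmptyInputError("clip boundary polygon is empty")
    keep, geoms = [], []
    for i, geom in enumerate(layer.geometries):
        clipped = shapely.intersection(geom, cutter)
        if layer.geometry_kind == "polygon":
            clipped = _polygonal(clipped)
            if clipped.is_empty or clipped.area <= 0:
                continue
        elif clipped.is_empty:
            continue
        keep.append(i)
        geoms.append(clipped)
    return VectorLayer(
        geoms,
        layer.attributes.iloc[keep].reset_index(drop=True),
        layer.crs,
        layer.geometry_kind,
    )


def buffer_dissolve_sensitive(merged: VectorLayer, buffer: float) -> SensitiveArea:
    """Step 6: expand every no-treatment polygon by the drift buffer, dissolve.

    The result is a single (multi)polygon feature; component_count records how
    many disjoint pieces the dissolved union has.
    """
    if merged.geometry_kind != "polygon":
        raise SchemaError("sensitive inputs must be polygons")
    if buffer < 0:
        raise MczonesError("buffer must be >= 0")
    if merged.is_empty:
        return SensitiveArea(shapely.Polygon(), 0, 0.0, merged.crs)
    if buffer > 0:
        expanded = [
            g.buffer(buffer, quad_segs=BUFFER_QUAD_SEGS) for g in merged.geometries
        ]
    else:
        expanded = list(merged.geometries)
    union = _polygonal(shapely.make_valid(shapely.union_all(expanded)))
    count = 1 if union.geom_type == "Polygon" else len(union.geoms)
    if union.is_empty:
        count = 0
    return SensitiveArea(union, count, union.area, merged.crs)


def build_fishnet(addresses: VectorLayer, config: PipelineConfig) -> list[GridCell]:
    """Step 8: square-cell grid anchored to the CRS origin, indexed to addresses.

    The origin snaps the address bounding box down to a multiple of the cell
    side, so cell boundaries do not depend on feature order.  By default only
    cells containing at least one address point (boundary inclusive) are
    retained; ``keep_empty_cells`` retains the full bounding block.
    """
    if addresses.geometry_kind != "point":
        raise SchemaError("fishnet is indexed to a point layer")
    if addresses.is_empty:
        raise EmptyInputError("address layer is empty; cannot index a fishnet grid")
    side = config.cell_side
    pts = np.vstack(
        [
            np.asarray([(p.x, p.y) for g in addresses.geometries for p in _points(g)])
        ]
    )
    cols = np.floor(pts[:, 0] / side).astype(np.int64)
    rows = np.floor(pts[:, 1] / side).astype(np.int64)
    ids = set(zip(rows.tolist(), cols.tolist()))
    # boundary-inclusive: a point exactly on a shared edge belongs to both cells
    on_x = pts[:, 0] % side == 0.0
    on_y = pts[:, 1] % side == 0.0
    for r, c in zip(rows[on_x].tolist(), cols[on_x].tolist()):
        ids.add((r, c - 1))
    for r, c in zip(rows[on_y].tolist(), cols[on_y].tolist()):
        ids.add((r - 1, c))
    for r, c in zip(rows[on_x & on_y].tolist(), cols[on_x & on_y].tolist()):
        ids.add((r - 1, c - 1))
    if config.keep_empty_cells:
        rmin, rmax = min(r for r, _ in ids), max(r for r, _ in ids)
        cmin, cmax = min(c for _, c in ids), max(c for _, c in ids)
        ids = {(r, c) for r in range(rmin, rmax + 1) for c in range(cmin, cmax + 1)}
    return [
        GridCell((r, c), box(c * side, r * side, (c + 1) * side, (r + 1) * side))
        for r, c in sorted(ids)
    ]


def _points(geom) -> Iterable:
    if geom.geom_type == "Point":
        return [geom]
    return list(geom.geoms)


def erase_sensitive(
    cells: list[GridCell], sensitive: SensitiveArea, sliver_min_area: float = 1.0
) -> list[GridCell]:
    """Step 9: subtract the sensitive area from every cell; drop empty slivers."""
    if sensitive.is_empty:
        return [GridCell(c.cell_id, c.geometry) for c in cells]
    out = []
    for cell in cells:
        remaining = _polygonal(
            shapely.difference(cell.geometry, sensitive.geometry)
        )
        if remaining.is_empty or remaining.area <= sliver_min_area:
            continue
        out.append(GridCell(cell.cell_id, remaining))
    return out


def classify_warning(
    cells: list[GridCell], sensitive: SensitiveArea, warning_distance: float
) -> tuple[list[GridCell], list[GridCell]]:
    """Steps 10-13: split post-erase cells into Warning and the inverted rest.

    A cell is Warning iff its post-erase geometry lies within (inclusive)
    warning_distance of the buffered sensitive area; cells that abut the
    erased boundary are at distance zero and always Warning.
    """
    warning, rest = [], []
    for cell in cells:
        if not sensitive.is_empty and (
            shapely.distance(cell.geometry, sensitive.geometry) <= warning_distance
        ):
            cell.type = CLASS_WARNING
            warning.append(cell)
        else:
            rest.append(cell)
    return warning, rest


def classify_remainder(
    rest: list[GridCell], wetlands: VectorLayer
) -> tuple[list[GridCell], list[GridCell]]:
    """Steps 14-16: wet non-warning cells are Approved, dry ones Not Significant.

    Intersection uses DE-9IM "intersects", so a boundary touch counts.
    """
    approved, not_significant = [], []
    tree = STRtree(wetlands.geometries) if len(wetlands) else None
    for cell in rest:
        wet = False
        if tree is not None:
            idx = tree.query(cell.geometry, predicate="intersects")
            wet = len(idx) > 0
        if wet:
            cell.type = CLASS_APPROVED
            approved.append(cell)
        else:
            cell.type = CLASS_NOT_SIGNIFICANT
            not_significant.append(cell)
    return approved, not_significant


def merge_classified(
    warning: list[GridCell],
    approved: list[GridCell],
    not_significant: list[GridCell],
    crs: int,
    config: PipelineConfig,
) -> ClassifiedGrid:
    """Step 17: combine the class selections into one fully classified grid."""
    seen: dict[tuple[int, int], str] = {}
    for group, name in (
        (warning, CLASS_WARNING),
        (approved, CLASS_APPROVED),
        (not_significant, CLASS_NOT_SIGNIFICANT),
    ):
        for cell in group:
            if cell.cell_id in seen:
                raise MczonesError(
                    f"cell {cell.cell_id} appears in both "
                    f"{seen[cell.cell_id]!r} and {name!r}"
                )
            seen[cell.cell_id] = name
            cell.type = name
    cells = sorted(warning + approved + not_significant, key=lambda c: c.cell_id)
    return ClassifiedGrid(cells, crs, config)


def attach_population(
    grid: ClassifiedGrid, blocks: VectorLayer, pop_field: str | None = None
) -> ClassifiedGrid:
    """Step 18: apportion census-block population onto the grid.

    ``area_weighted`` (default) assigns each cell
    sum_b pop_b * area(cell ∩ b) / area(b), which conserves population over
    the grid's coverage of each block.  ``block_copy`` copies the full
    population of every intersecting block into each cell (documented
    over-counting, mirroring a plain GIS intersect-join).
    """
    col = pop_field or _find_pop_field(blocks)
    pops = pd.to_numeric(blocks.attributes[col]).to_numpy(dtype=float)
    if (pops < 0).any():
        raise MczonesError(f"negative population in attribute {col!r}")
    mode = grid.config.apportionment
    for cell in grid.cells:
        cell.population = 0.0
    if len(blocks) and len(grid.cells):
        tree = STRtree([c.geometry for c in grid.cells])
        for geom, pop in zip(blocks.geometries, pops):
            idx = tree.query(geom, predicate="intersects")
            if len(idx) == 0:
                continue
            if mode == "block_copy":
                for i in idx:
                    grid.cells[i].population += float(pop)
                continue
            block_area = geom.area
            if block_area <= 0:
                continue
            for i in idx:
                overlap = shapely.intersection(
                    grid.cells[i].geometry, geom
                ).area
                if overlap > 0:
                    grid.cells[i].population += float(pop) * overlap / block_area
    for cell in grid.cells:
        cell.density = cell.population / cell.area if cell.area > 0 else 0.0
    return grid


def _find_pop_field(blocks: VectorLayer) -> str:
    for col in blocks.attributes.columns:
        if "pop" in str(col).lower():
            return col
    raise SchemaError(
        f"no population attribute found among {list(blocks.attributes.columns)}"
    )


def summarize_zones(grid: ClassifiedGrid) -> ZoneSummary:
    """Per-class area (mi2 at 2 dp, acres = mi2 x 640), cell counts, population."""
    ft = unit_to_us_feet(grid.crs)
    summary = ZoneSummary({name: ClassTotals() for name in CLASSES})
    for cell in grid.cells:
        if cell.type not in summary.classes:
            raise MczonesError(f"cell {cell.cell_id} has unset/unknown type")
        t = summary.classes[cell.type]
        t.area_ft2 += cell.area * ft * ft
        t.cell_count += 1
        t.population += cell.population
    return summary


def estimate_treatment_cost(
    summary: ZoneSummary, cost_per_acre: float, product_rate: float
) -> CostReport:
    """Scope-of-work projection from the vetted (Approved + Warning) acres."""
    if cost_per_acre < 0 or product_rate < 0:
        raise MczonesError("cost_per_acre and product_rate must be >= 0")
    return CostReport(summary.treatable.area_acres, cost_per_acre, product_rate)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    layers: Mapping[str, VectorLayer],
    config: PipelineConfig,
    step_log: list | None = None,
) -> tuple[ClassifiedGrid, ZoneSummary]:
    """Execute steps 1-18 and return the classified grid plus its summary.

    All required layers must already share ``config.working_crs`` and be
    validity-repaired (see :func:`prepare_layers`).  Deterministic: identical
    inputs and config give identical output.
    """
    missing = [k for k in REQUIRED_LAYERS if k not in layers]
    if missing:
        raise PipelineError(1, f"missing required layer(s): {missing}")
    check_common_crs(
        [layers[k] for k in REQUIRED_LAYERS], expected=config.working_crs
    )

    def _stage(step: int, label: str, fn, *args):
        try:
            result = fn(*args)
        except MczonesError as exc:
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(step, f"{label}: {exc}") from exc
        if step_log is not None:
            n = (
                len(result)
                if hasattr(result, "__len__")
                else getattr(result, "component_count", 1)
            )
            step_log.append({"step": step, "stage": label, "features": n})
        return result

    county = _stage(1, "select county", select_county, layers["counties"],
                    config.county_name)
    heritage = _stage(2, "filter heritage", filter_heritage, layers["heritage"],
                      config)
    hydro = _stage(3, "buffer hydro lines", buffer_hydro_lines, layers["streams"],
                   config.hydro_half_width) if len(layers["streams"]) else (
        VectorLayer.from_records([], None, config.working_crs, "polygon"))
    merged = _stage(4, "merge sensitive inputs", merge_layers,
                    [layers["waterbodies"], hydro, heritage])
    clipped = _stage(5, "clip to county", clip_layer, merged, county)
    sensitive = _stage(6, "buffer + dissolve sensitive", buffer_dissolve_sensitive,
                       clipped, config.sensitive_buffer)
    wetlands = _stage(7, "clip wetlands", clip_layer, layers["wetlands"], county)
    cells = _stage(8, "build fishnet", build_fishnet, layers["addresses"], config)
    remaining = _stage(9, "erase sensitive", erase_sensitive, cells, sensitive,
                       config.sliver_min_area)
    if not remaining:
        log.warning(
            "sensitive area covers the whole grid; classified grid is empty"
        )
    warning, rest = _stage(10, "classify warning", classify_warning, remaining,
                           sensitive, config.warning_distance)
    approved, not_significant = _stage(13, "classify remainder",
                                       classify_remainder, rest, wetlands)
    grid = _stage(17, "merge classes", merge_classified, warning, approved,
                  not_significant, config.working_crs, config)
    grid = _stage(18, "attach population", attach_population, grid,
                  layers["blocks"])
    return grid, summarize_zones(grid)


def prepare_layers(
    layers: Mapping[str, VectorLayer], config: PipelineConfig
) -> dict[str, VectorLayer]:
    """Reproject every layer to the working CRS and validity-repair it."""
    from .gis_io import reproject

    out = {}
    for name, layer in layers.items():
        if layer.crs != config.working_crs:
            layer = reproject(layer, config.working_crs)
        out[name] = repair(layer)[0]
    return out
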