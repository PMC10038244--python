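"""Synthetic county bundles and an independent raster classification oracle.

The generator emulates the layer inventory a county GIS office would pull
from a statewide portal: a county boundary, protected-land polygons carrying
GAP_STATUS / OWNER_TYPE management codes, stream centerlines crossing the
county, lake and wetland polygons, clustered address points, and a tiling of
census blocks with populations.  A fixed seed fully determines the bundle.

The raster oracle re-derives the per-class areas at a fine pixel resolution
using point-in-region sampling and distance transforms, aggregated to cells
with the same rules the vector pipeline applies.  It shares only the upstream
sensitive-area construction with the pipeline; erase accounting, warning
distances, wetness and areas are computed independently, so agreement is a
genuine two-route check on steps 9-17.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, box

from .config import MI2_IN_SQFT, PipelineConfig
from .errors import GenerationError, MczonesError
from .layers import VectorLayer
from .pipeline import (
    CLASS_APPROVED,
    CLASS_NOT_SIGNIFICANT,
    CLASS_WARNING,
    build_fishnet,
    buffer_dissolve_sensitive,
    buffer_hydro_lines,
    clip_layer,
    filter_heritage,
    merge_layers,
    select_county,
)

FT_PER_MI = 5280.0

GAP_VOCABULARY = [
    "1: Managed for biodiversity; disturbance events proceed or mimicked",
    "2: Managed for biodiversity; disturbance events suppressed",
    "3: Managed for multiple uses",
    "4: No known mandate for protection",
]
OWNER_VOCABULARY = ["State Land", "Federal Land", "Local Government", "Private"]

COUNTY_NAME = "Synthetic"


@dataclass
class CountyParams:
    """Knobs of the generated county; the seed fully determines the bundle."""

    side: float = 10.0 * FT_PER_MI  # square county edge, working-CRS feet
    n_rivers: int = 4
    n_lakes: int = 6
    wetland_fraction: float = 0.35
    n_preserves: int = 4
    n_addresses: int = 400
    address_clustering: str = "clustered"  # or "uniform"
    block_grid: int = 8
    seed: int = 0
    working_crs: int = 2264

    def __post_init__(self):
        if self.side <= 0:
            raise GenerationError("side must be > 0")
        if not 0.0 <= self.wetland_fraction <= 1.0:
            raise GenerationError("wetland_fraction must lie in [0, 1]")
        for name in ("n_rivers", "n_lakes", "n_preserves", "n_addresses",
                     "block_grid"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")
        if self.address_clustering not in ("uniform", "clustered"):
            raise GenerationError(
                f"address_clustering must be 'uniform' or 'clustered', "
                f"got {self.address_clustering!r}"
            )


@dataclass
class ReferenceAreas:
    """Per-class areas from the raster oracle, in working-CRS square units."""

    areas: dict[str, float]
    excluded_area: float
    resolution: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": k, "area_unit2": v, "area_mi2": v / MI2_IN_SQFT}
            for k, v in self.areas.items()
        ]
        rows.append(
            {
                "class": "Excluded",
                "area_unit2": self.excluded_area,
                "area_mi2": self.excluded_area / MI2_IN_SQFT,
            }
        )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generator


def _river(rng: np.random.Generator, side: float) -> LineString:
    """A smoothed random walk crossing the county from one edge to the other."""
    horizontal = bool(rng.integers(0, 2))
    n = 24
    along = np.linspace(-0.02 * side, 1.02 * side, n)
    across = np.empty(n)
    across[0] = rng.uniform(0.15, 0.85) * side
    steps = rng.normal(0.0, 0.045 * side, size=n - 1)
    across[1:] = across[0] + np.cumsum(steps)
    across = np.clip(across, 0.03 * side, 0.97 * side)
    # midpoint smoothing pass keeps bends gentle
    for _ in range(2):
        across[1:-1] = 0.25 * across[:-2] + 0.5 * across[1:-1] + 0.25 * across[2:]
    pts = np.column_stack([along, across] if horizontal else [across, along])
    return LineString(pts)


def _blob(rng: np.random.Generator, side: float, radius: float) -> Polygon:
    center = rng.uniform(0.05 * side, 0.95 * side, size=2)
    r = radius * rng.uniform(0.6, 1.4)
    blob = Point(center).buffer(r, quad_segs=16)
    sx, sy = rng.uniform(0.7, 1.4, size=2)
    return shapely.affinity.scale(blob, sx, sy, origin=tuple(center))


def _wetlands(
    rng: np.random.Generator, county: Polygon, side: float, fraction: float
) -> list[Polygon]:
    """Buffered random blobs scaled by bisection to hit the target fraction."""
    if fraction <= 0:
        return []
    target = fraction * county.area
    centers = rng.uniform(0.05 * side, 0.95 * side, size=(14, 2))
    aspect = rng.uniform(0.7, 1.4, size=(14, 2))
    base = rng.uniform(0.5, 1.5, size=14)

    def union_at(scale: float):
        blobs = []
        for c, (sx, sy), b in zip(centers, aspect, base):
            blob = Point(c).buffer(max(b * scale, 1e-6), quad_segs=16)
            blobs.append(shapely.affinity.scale(blob, sx, sy, origin=tuple(c)))
        return shapely.intersection(shapely.union_all(blobs), county)

    lo, hi = 0.0, 0.02 * side
    for _ in range(60):
        if union_at(hi).area >= target:
            break
        hi *= 2.0
    else:
        raise GenerationError(
            f"cannot reach wetland_fraction={fraction}: county saturated"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        area = union_at(mid).area
        if abs(area - target) <= 0.02 * target:
            lo = hi = mid
            break
        if area < target:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    achieved = union_at(scale).area
    if abs(achieved - target) > 0.02 * target:
        raise GenerationError(
            f"wetland scaling did not converge: target {target:.3g}, "
            f"achieved {achieved:.3g}"
        )
    blobs = []
    for c, (sx, sy), b in zip(centers, aspect, base):
        blob = Point(c).buffer(max(b * scale, 1e-6), quad_segs=16)
        blobs.append(shapely.affinity.scale(blob, sx, sy, origin=tuple(c)))
    out = []
    for blob in blobs:
        clipped = shapely.intersection(blob, county)
        if not clipped.is_empty and clipped.area > 0:
            out.append(clipped)
    return out


def generate_county(params: CountyParams) -> dict[str, VectorLayer]:
    """Generate a deterministic named-layer bundle for one synthetic county."""
    rng = np.random.default_rng(params.seed)
    side = params.side
    crs = params.working_crs
    county_poly = box(0.0, 0.0, side, side)

    counties = VectorLayer.from_records(
        [county_poly], [{"County": COUNTY_NAME}], crs, "polygon"
    )

    rivers = [_river(rng, side) for _ in range(params.n_rivers)]
    streams = VectorLayer.from_records(
        [shapely.intersection(r, county_poly) for r in rivers],
        [{"NAME": f"River {i}"} for i in range(params.n_rivers)],
        crs,
        "line",
    )

    lakes = [
        shapely.intersection(_blob(rng, side, 0.02 * side), county_poly)
        for _ in range(params.n_lakes)
    ]
    waterbodies = VectorLayer.from_records(
        lakes, [{"NAME": f"Lake {i}"} for i in range(params.n_lakes)], crs, "polygon"
    )

    preserves, records = [], []
    for i in range(params.n_preserves):
        w, h = rng.uniform(0.05, 0.15, size=2) * side
        x0 = rng.uniform(0, side - w)
        y0 = rng.uniform(0, side - h)
        preserves.append(box(x0, y0, x0 + w, y0 + h))
        # first preserve always kept so every county has protected land;
        # the rest cycle through the vocabulary to exercise the filter
        gap = GAP_VOCABULARY[0] if i == 0 else GAP_VOCABULARY[i % len(GAP_VOCABULARY)]
        owner = OWNER_VOCABULARY[int(rng.integers(0, len(OWNER_VOCABULARY)))]
        records.append({"NAME": f"Preserve {i}", "GAP_STATUS": gap,
                        "OWNER_TYPE": owner})
    heritage = VectorLayer.from_records(preserves, records, crs, "polygon")

    wetland_polys = _wetlands(rng, county_poly, side, params.wetland_fraction)
    wetlands = VectorLayer.from_records(
        wetland_polys,
        [{"WETLAND_ID": i} for i in range(len(wetland_polys))],
        crs,
        "polygon",
    )

    n = params.n_addresses
    if params.address_clustering == "uniform" or n == 0:
        pts = rng.uniform(0.0, side, size=(n, 2))
    else:
        k = max(3, n // 100)
        centers = rng.uniform(0.1 * side, 0.9 * side, size=(k, 2))
        choice = rng.integers(0, k, size=n)
        pts = centers[choice] + rng.normal(0.0, 0.05 * side, size=(n, 2))
        pts = np.clip(pts, 0.0, np.nextafter(side, 0.0))
    addresses = VectorLayer.from_records(
        [Point(p) for p in pts], [{"ADDR_ID": i} for i in range(n)], crs, "point"
    )

    nb = max(params.block_grid, 1)
    bs = side / nb
    block_geoms, block_recs = [], []
    for r in range(nb):
        for c in range(nb):
            block_geoms.append(box(c * bs, r * bs, (c + 1) * bs, (r + 1) * bs))
            pop = int(round(10.0 ** rng.uniform(1.0, 3.0)))  # log-uniform 10..1000
            block_recs.append({"BLOCK_ID": f"{r:02d}{c:02d}", "POPULATION": pop})
    blocks = VectorLayer.from_records(block_geoms, block_recs, crs, "polygon")

    return {
        "counties": counties,
        "heritage": heritage,
        "streams": streams,
        "waterbodies": waterbodies,
        "wetlands": wetlands,
        "addresses": addresses,
        "blocks": blocks,
    }


def default_config(params: CountyParams | None = None, **overrides) -> PipelineConfig:
    """Pipeline configuration matching a generated bundle."""
    crs = params.working_crs if params is not None else 2264
    kwargs = dict(county_name=COUNTY_NAME, working_crs=crs)
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# hand-constructed fixture


def expected_simple_case() -> tuple[dict[str, VectorLayer], dict[tuple[int, int], str]]:
    """A 5x5-cell county whose classification is hand-derivable.

    One preserve exactly fills the centre cell, so the 100-ft drift buffer
    erases it completely and bites ~100 ft into each of the eight surrounding
    cells, which therefore sit at distance zero and classify as Warning.  A
    wetland strip covers the west column (stopping 280 ft short of the column
    boundary so no other cell touches it): its five cells are Approved.  The
    remaining eleven cells are Not Significant.  An address sits at every cell
    centre, so all 25 cells enter the grid and 24 survive the erase.
    """
    cell = FT_PER_MI
    side = 5 * cell
    crs = 2264
    county_poly = box(0.0, 0.0, side, side)
    counties = VectorLayer.from_records(
        [county_poly], [{"County": COUNTY_NAME}], crs, "polygon"
    )
    heritage = VectorLayer.from_records(
        [box(2 * cell, 2 * cell, 3 * cell, 3 * cell)],
        [{"NAME": "Center preserve", "GAP_STATUS": GAP_VOCABULARY[0],
          "OWNER_TYPE": "State Land"}],
        crs,
        "polygon",
    )
    wetlands = VectorLayer.from_records(
        [box(0.0, 0.0, cell - 280.0, side)],
        [{"WETLAND_ID": 0}],
        crs,
        "polygon",
    )
    streams = VectorLayer.from_records([], None, crs, "line")
    waterbodies = VectorLayer.from_records([], None, crs, "polygon")
    addresses = VectorLayer.from_records(
        [
            Point((c + 0.5) * cell, (r + 0.5) * cell)
            for r in range(5)
            for c in range(5)
        ],
        [{"ADDR_ID": i} for i in range(25)],
        crs,
        "point",
    )
    blocks = VectorLayer.from_records(
        [county_poly], [{"BLOCK_ID": "0000", "POPULATION": 2500}], crs, "polygon"
    )

    expected: dict[tuple[int, int], str] = {}
    for r in range(5):
        for c in range(5):
            if (r, c) == (2, 2):
                continue  # erased
            if abs(r - 2) <= 1 and abs(c - 2) <= 1:
                expected[(r, c)] = CLASS_WARNING
            elif c == 0:
                expected[(r, c)] = CLASS_APPROVED
            else:
                expected[(r, c)] = CLASS_NOT_SIGNIFICANT

    layers = {
        "counties": counties,
        "heritage": heritage,
        "streams": streams,
        "waterbodies": waterbodies,
        "wetlands": wetlands,
        "addresses": addresses,
        "blocks": blocks,
    }
    return layers, expected


# ---------------------------------------------------------------------------
# raster oracle


def raster_oracle(
    layers: dict[str, VectorLayer],
    config: PipelineConfig,
    resolution: float,
) -> ReferenceAreas:
    """Re-derive per-class areas on a fine pixel raster.

    Pixel centres over the retained fishnet extent are labelled: inside the
    sensitive area -> excluded; else Warning when their cell's treatable
    region lies within the warning distance of the sensitive area (distance
    transform, with exact geometric refinement for cells whose estimated
    distance falls within two pixels of the threshold, so pixel quantization
    cannot flip a whole cell's class); else Approved when the cell has a wet
    treatable pixel; else Not Significant.  Areas are pixel counts times the
    pixel area.
    """
    side = config.cell_side
    if resolution > side / 100.0:
        raise MczonesError(
            f"oracle resolution {resolution} too coarse; need <= {side / 100.0}"
        )

    county = select_county(layers["counties"], config.county_name)
    heritage = filter_heritage(layers["heritage"], config)
    if len(layers["streams"]):
        hydro = buffer_hydro_lines(layers["streams"], config.hydro_half_width)
    else:
        hydro = VectorLayer.from_records([], None, config.working_crs, "polygon")
    merged = merge_layers([layers["waterbodies"], hydro, heritage])
    clipped = clip_layer(merged, county)
    sensitive = buffer_dissolve_sensitive(clipped, config.sensitive_buffer)
    wetlands = clip_layer(layers["wetlands"], county)
    cells = build_fishnet(layers["addresses"], config)

    retained = {c.cell_id for c in cells}
    rows = np.array([r for r, _ in retained])
    cols = np.array([c for _, c in retained])
    pad = config.warning_distance + 2.0 * resolution
    x0 = cols.min() * side - pad
    x1 = (cols.max() + 1) * side + pad
    y0 = rows.min() * side - pad
    y1 = (rows.max() + 1) * side + pad
    nx = int(math.ceil((x1 - x0) / resolution))
    ny = int(math.ceil((y1 - y0) / resolution))
    xs = x0 + (np.arange(nx) + 0.5) * resolution
    ys = y0 + (np.arange(ny) + 0.5) * resolution
    px_col = np.floor(xs / side).astype(np.int64)
    px_row = np.floor(ys / side).astype(np.int64)

    # in-grid mask by exact index arithmetic (cells are lattice squares)
    key = lambda r, c: (r - rows.min()) * (cols.max() - cols.min() + 2) + (
        c - cols.min()
    )
    retained_keys = np.array(sorted(key(r, c) for r, c in retained))
    px_keys = key(px_row[:, None], px_col[None, :])
    in_range = (
        (px_row[:, None] >= rows.min())
        & (px_row[:, None] <= rows.max())
        & (px_col[None, :] >= cols.min())
        & (px_col[None, :] <= cols.max())
    )
    in_grid = in_range & np.isin(px_keys, retained_keys)

    sens_mask = _region_mask(sensitive.geometry, xs, ys)
    wet_mask = _region_mask(
        shapely.union_all(wetlands.geometries) if len(wetlands) else None, xs, ys
    )

    if sens_mask.any():
        dist = ndimage.distance_transform_edt(~sens_mask, sampling=resolution)
    else:
        dist = np.full((ny, nx), np.inf)

    treat = in_grid & ~sens_mask
    # aggregate per cell
    cell_index = {cid: i for i, cid in enumerate(sorted(retained))}
    n_cells = len(cell_index)
    flat_cell = np.full((ny, nx), -1, dtype=np.int64)
    lut = {key(r, c): i for (r, c), i in cell_index.items()}
    lut_arr = np.full(int(retained_keys.max()) + 1 if len(retained_keys) else 1, -1)
    for k, i in lut.items():
        lut_arr[k] = i
    valid = in_grid
    flat_cell[valid] = lut_arr[px_keys[valid]]

    treat_idx = flat_cell[treat]
    treat_counts = np.bincount(treat_idx, minlength=n_cells)
    min_dist = np.full(n_cells, np.inf)
    np.minimum.at(min_dist, treat_idx, dist[treat])
    wet_any = np.zeros(n_cells, dtype=bool)
    np.logical_or.at(wet_any, flat_cell[treat & wet_mask],
                     np.ones(int((treat & wet_mask).sum()), dtype=bool))

    # exact refinement at the warning threshold and for wetness near-misses
    wd = config.warning_distance
    ids_sorted = sorted(retained)
    if not sensitive.is_empty:
        band = np.abs(min_dist - wd) <= 2.0 * resolution
        for i in np.nonzero(band)[0]:
            r, c = ids_sorted[i]
            cell_box = box(c * side, r * side, (c + 1) * side, (r + 1) * side)
            remaining = shapely.difference(cell_box, sensitive.geometry)
            if remaining.is_empty:
                min_dist[i] = np.inf
            else:
                min_dist[i] = shapely.distance(remaining, sensitive.geometry)
    if len(wetlands):
        wet_union = shapely.union_all(wetlands.geometries)
        wet_dist = (
            ndimage.distance_transform_edt(~wet_mask, sampling=resolution)
            if wet_mask.any()
            else np.full((ny, nx), np.inf)
        )
        near_wet = np.zeros(n_cells, dtype=bool)
        near_vals = wet_dist[treat]
        near_min = np.full(n_cells, np.inf)
        np.minimum.at(near_min, treat_idx, near_vals)
        near_wet = (~wet_any) & (near_min <= 2.0 * resolution * math.sqrt(2.0))
        for i in np.nonzero(near_wet)[0]:
            r, c = ids_sorted[i]
            cell_box = box(c * side, r * side, (c + 1) * side, (r + 1) * side)
            remaining = (
                shapely.difference(cell_box, sensitive.geometry)
                if not sensitive.is_empty
                else cell_box
            )
            wet_any[i] = (not remaining.is_empty) and shapely.intersects(
                remaining, wet_union
            )

    alive = treat_counts > 0
    warning_cells = alive & (min_dist <= wd) & np.isfinite(min_dist)
    approved_cells = alive & ~warning_cells & wet_any
    notsig_cells = alive & ~warning_cells & ~wet_any

    px_area = resolution * resolution
    areas = {
        CLASS_APPROVED: float(treat_counts[approved_cells].sum()) * px_area,
        CLASS_WARNING: float(treat_counts[warning_cells].sum()) * px_area,
        CLASS_NOT_SIGNIFICANT: float(treat_counts[notsig_cells].sum()) * px_area,
    }
    excluded = float((in_grid & sens_mask).sum()) * px_area
    return ReferenceAreas(areas, excluded, resolution)


def _region_mask(geom, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pixel-centre membership mask for a polygonal region, bbox-windowed."""
    mask = np.zeros((len(ys), len(xs)), dtype=bool)
    if geom is None or geom.is_empty:
        return mask
    minx, miny, maxx, maxy = geom.bounds
    ix = np.nonzero((xs >= minx) & (xs <= maxx))[0]
    iy = np.nonzero((ys >= miny) & (ys <= maxy))[0]
    if len(ix) == 0 or len(iy) == 0:
        return mask
    shapely.prepare(geom)
    gx, gy = np.meshgrid(xs[ix], ys[iy])
    mask[np.ix_(iy, ix)] = shapely.intersects_xy(geom, gx.ravel(), gy.ravel()).reshape(
        gx.shape
    )
    return mask
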