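"""Human-readable outputs: summary CSV, run manifest, and a basic map export."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .pipeline import (
    CLASS_APPROVED,
    CLASS_NOT_SIGNIFICANT,
    CLASS_WARNING,
    ClassifiedGrid,
    ZoneSummary,
)

CLASS_COLORS = {
    CLASS_APPROVED: "#2e8b57",  # green
    CLASS_WARNING: "#c62828",  # red
    CLASS_NOT_SIGNIFICANT: "#9e9e9e",
}


def write_summary_csv(summary: ZoneSummary, path) -> None:
    summary.to_frame().to_csv(path, index=False, lineterminator="\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    config_snapshot: dict,
    input_paths: dict,
    step_log: list,
    status: str,
    error: str | None = None,
) -> None:
    """Reproducibility record written on every run, success or failure."""
    manifest = {
        "software": {"name": "mczones", "version": __version__},
        "status": status,
        "config": config_snapshot,
        "inputs": {
            role: {"path": str(p), "sha256": sha256_of(p) if Path(p).exists() else None}
            for role, p in input_paths.items()
        },
        "steps": step_log,
    }
    if error:
        manifest["error"] = error
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def _polygon_patches(geom):
    from matplotlib.path import Path as MplPath

    polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
    vertices, codes = [], []
    for poly in polys:
        for ring in [poly.exterior, *poly.interiors]:
            pts = np.asarray(ring.coords)
            vertices.append(pts)
            codes.append(
                [MplPath.MOVETO] + [MplPath.LINETO] * (len(pts) - 2) + [MplPath.CLOSEPOLY]
            )
    return MplPath(np.vstack(vertices), np.concatenate(codes))


def export_map(grid: ClassifiedGrid, path, show_population: bool = False) -> None:
    """PNG overview: Approved green, Warning red; optional white-to-purple
    population choropleth underneath the class outlines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap
    from matplotlib.patches import PathPatch

    fig, ax = plt.subplots(figsize=(8, 8))
    if show_population:
        cmap = LinearSegmentedColormap.from_list(
            "pop", ["#ffffff", "#3f0d66"]
        )  # white -> dark purple
        dmax = max((c.density for c in grid.cells), default=0.0) or 1.0
        for cell in grid.cells:
            ax.add_patch(
                PathPatch(
                    _polygon_patches(cell.geometry),
                    facecolor=cmap(cell.density / dmax),
                    edgecolor="none",
                )
            )
        for cell in grid.cells:
            if cell.type in (CLASS_APPROVED, CLASS_WARNING):
                ax.add_patch(
                    PathPatch(
                        _polygon_patches(cell.geometry),
                        facecolor="none",
                        edgecolor=CLASS_COLORS[cell.type],
                        linewidth=0.8,
                    )
                )
    else:
        for cell in grid.cells:
            ax.add_patch(
                PathPatch(
                    _polygon_patches(cell.geometry),
                    facecolor=CLASS_COLORS.get(cell.type, "#cccccc"),
                    edgecolor="white",
                    linewidth=0.2,
                )
            )
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_title("Treatment zones")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
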