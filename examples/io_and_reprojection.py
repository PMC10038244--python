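"""Read/write layers in three formats and reproject geographic input.

Source layers often arrive in geographic coordinates (EPSG:4269 degrees);
every pipeline distance is in the working CRS's linear unit, so layers are
reprojected to NC State Plane feet (EPSG:2264) first.  The same layer is then
round-tripped through GeoJSON, Shapefile and GeoPackage.
"""

import tempfile
from pathlib import Path

from shapely.geometry import Point

import mczones as mz

towns = mz.VectorLayer.from_records(
    [Point(-78.0, 34.3), Point(-78.3, 34.5)],
    [{"NAME": "Southport"}, {"NAME": "Bolivia"}],
    crs=4269,
    geometry_kind="point",
)
planar = mz.reproject(towns, 2264)
for name, geom in zip(planar.column("NAME"), planar.geometries):
    print(f"{name:10s} -> ({geom.x:12.1f}, {geom.y:12.1f}) ftUS")
d_mi = planar.geometries[0].distance(planar.geometries[1]) / 5280.0
print(f"separation: {d_mi:.2f} mi in the projected plane")

with tempfile.TemporaryDirectory() as tmp:
    for ext in ("geojson", "shp", "gpkg"):
        path = Path(tmp) / f"towns.{ext}"
        mz.write_layer(planar, path)
        back = mz.read_layer(path)
        print(f"{ext:8s} round-trip: {len(back)} features, EPSG:{back.crs}")
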