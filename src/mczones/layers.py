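"""VectorLayer: the feature-collection currency passed between pipeline stages.

A layer is a list of shapely geometries of one geometric kind (point, line or
polygon; multi-part variants allowed), a positionally aligned pandas attribute
table, and an EPSG code.  Attribute lookup is case-insensitive, since the
attribute casing of shapefile dialects varies; the stored casing is preserved
on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry.base import BaseGeometry

from .errors import CRSError, SchemaError

KIND_OF_TYPE = {
    "Point": "point",
    "MultiPoint": "point",
    "LineString": "line",
    "MultiLineString": "line",
    "LinearRing": "line",
    "Polygon": "polygon",
    "MultiPolygon": "polygon",
}

GEOMETRY_KINDS = ("point", "line", "polygon")


def kind_of(geom: BaseGeometry) -> str:
    try:
        return KIND_OF_TYPE[geom.geom_type]
    except KeyError:
        raise SchemaError(f"unsupported geometry type {geom.geom_type!r}") from None


@dataclass
class VectorLayer:
    geometries: list[BaseGeometry]
    attributes: pd.DataFrame
    crs: int
    geometry_kind: str = ""

    def __post_init__(self):
        if self.crs is None:
            raise CRSError("VectorLayer requires a CRS (EPSG code)")
        self.crs = int(self.crs)
        if self.attributes is None:
            self.attributes = pd.DataFrame(index=range(len(self.geometries)))
        if len(self.attributes) != len(self.geometries):
            raise SchemaError(
                f"attribute table length {len(self.attributes)} != "
                f"geometry count {len(self.geometries)}"
            )
        self.attributes = self.attributes.reset_index(drop=True)
        kinds = {kind_of(g) for g in self.geometries if not g.is_empty}
        if len(kinds) > 1:
            raise SchemaError(f"mixed geometry kinds in one layer: {sorted(kinds)}")
        if kinds:
            inferred = kinds.pop()
            if self.geometry_kind and self.geometry_kind != inferred:
                raise SchemaError(
                    f"declared kind {self.geometry_kind!r} != geometries ({inferred})"
                )
            self.geometry_kind = inferred
        elif not self.geometry_kind:
            raise SchemaError("empty layer requires an explicit geometry_kind")
        if self.geometry_kind not in GEOMETRY_KINDS:
            raise SchemaError(f"unknown geometry_kind {self.geometry_kind!r}")

    @classmethod
    def from_records(
        cls,
        geometries: Iterable[BaseGeometry],
        records: Sequence[Mapping] | None,
        crs: int,
        geometry_kind: str = "",
    ) -> "VectorLayer":
        geoms = list(geometries)
        table = pd.DataFrame.from_records(records) if records else None
        if table is None or table.empty:
            table = pd.DataFrame(index=range(len(geoms)))
        return cls(geoms, table, crs, geometry_kind)

    def __len__(self) -> int:
        return len(self.geometries)

    @property
    def is_empty(self) -> bool:
        return len(self.geometries) == 0

    def find_column(self, name: str) -> str | None:
        """Return the stored column name matching *name* case-insensitively."""
        low = name.strip().lower()
        for col in self.attributes.columns:
            if str(col).strip().lower() == low:
                return col
        return None

    def column(self, name: str) -> pd.Series:
        col = self.find_column(name)
        if col is None:
            raise SchemaError(f"layer has no attribute {name!r}")
        return self.attributes[col]

    def subset(self, mask) -> "VectorLayer":
        idx = [i for i, keep in enumerate(mask) if keep]
        return VectorLayer(
            [self.geometries[i] for i in idx],
            self.attributes.iloc[idx].reset_index(drop=True),
            self.crs,
            self.geometry_kind,
        )

    def copy(self) -> "VectorLayer":
        return VectorLayer(
            list(self.geometries), self.attributes.copy(), self.crs, self.geometry_kind
        )


@dataclass
class LayerSchema:
    """Required attributes (name, kind in {'text','number'}) and geometry kind."""

    required_attributes: list[tuple[str, str]] = field(default_factory=list)
    geometry_kind: str = ""

    def validate(self, layer: VectorLayer) -> None:
        if self.geometry_kind and layer.geometry_kind != self.geometry_kind:
            raise SchemaError(
                f"expected {self.geometry_kind} geometry, got {layer.geometry_kind}"
            )
        for name, value_kind in self.required_attributes:
            col = layer.find_column(name)
            if col is None:
                raise SchemaError(f"required attribute {name!r} is missing")
            if value_kind == "number" and len(layer):
                if not pd.api.types.is_numeric_dtype(layer.attributes[col]):
                    try:
                        pd.to_numeric(layer.attributes[col])
                    except (ValueError, TypeError):
                        raise SchemaError(
                            f"attribute {name!r} must be numeric"
                        ) from None


HERITAGE_SCHEMA = LayerSchema(
    [("GAP_STATUS", "text"), ("OWNER_TYPE", "text")], "polygon"
)
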