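"""Pipeline configuration.

All distances and areas are interpreted in the linear unit of the working
CRS.  The defaults encode the published protocol parameters for a feet-based
CRS: 50 ft stream half-width, 100 ft sensitive-area drift buffer, 100 ft
warning distance, and 1 mi2 (5280 ft side) grid cells.  A geographic
(degree) working CRS is rejected because buffer distances would be
meaningless.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import crs as crs_mod
from .errors import ConfigError

MI2_IN_SQFT = 5280.0 * 5280.0  # 27 878 400

APPORTIONMENT_MODES = ("area_weighted", "block_copy")


@dataclass
class PipelineConfig:
    county_name: str
    gap_keep_values: list = field(default_factory=lambda: [1, 2])
    owner_keep_values: list = field(default_factory=lambda: ["federal land"])
    hydro_half_width: float = 50.0
    sensitive_buffer: float = 100.0
    warning_distance: float = 100.0
    cell_area: float = MI2_IN_SQFT
    keep_empty_cells: bool = False
    apportionment: str = "area_weighted"
    sliver_min_area: float = 1.0
    working_crs: int = 2264

    def __post_init__(self):
        if not str(self.county_name).strip():
            raise ConfigError("county_name must be non-empty")
        for name in ("hydro_half_width", "sensitive_buffer", "warning_distance"):
            value = float(getattr(self, name))
            if not (value >= 0 and math.isfinite(value)):
                raise ConfigError(f"{name} must be finite and >= 0, got {value}")
            setattr(self, name, value)
        for name in ("cell_area", "sliver_min_area"):
            value = float(getattr(self, name))
            if not (value > 0 and math.isfinite(value)):
                raise ConfigError(f"{name} must be finite and > 0, got {value}")
            setattr(self, name, value)
        if not math.isfinite(self.cell_side):
            raise ConfigError("cell_area yields a non-finite cell side")
        if self.apportionment not in APPORTIONMENT_MODES:
            raise ConfigError(
                f"apportionment must be one of {APPORTIONMENT_MODES}, "
                f"got {self.apportionment!r}"
            )
        self.working_crs = int(self.working_crs)
        if crs_mod.is_geographic(self.working_crs):
            raise ConfigError(
                f"working_crs EPSG:{self.working_crs} is geographic; "
                "a projected CRS with a linear unit is required"
            )

    @property
    def cell_side(self) -> float:
        return math.sqrt(self.cell_area)

    def snapshot(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**mapping)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path) -> PipelineConfig:
    """Load a flat YAML key/value file mirroring PipelineConfig field names."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} must be a flat key/value mapping")
    return PipelineConfig.from_mapping(doc)
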