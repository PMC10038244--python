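"""Coordinate reference systems and reprojection.

The toolkit works in a projected CRS whose linear unit carries all buffer
distances and areas; the pipeline defaults to NC State Plane (EPSG:2264,
US survey feet) because the protocol's parameters are stated in feet and
square miles.  A small self-contained registry supports the geographic CRSs
the source layers typically arrive in (EPSG:4326 / 4269) and the two NC
State Plane variants (EPSG:2264 ftUS, EPSG:32119 m), implemented with the
standard ellipsoidal Lambert Conformal Conic (2SP) forward/inverse formulas.

NAD83 and WGS84 realizations differ by under ~2 m; the registry treats the
datum shift as identity, which is far below the 1-mi2 cell scale the
pipeline operates at.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CRSError

US_SURVEY_FOOT_M = 1200.0 / 3937.0  # exact definition
SQFT_PER_MI2 = 5280.0 * 5280.0
ACRES_PER_MI2 = 640.0


@dataclass(frozen=True)
class Ellipsoid:
    a: float  # semi-major axis, metres
    inv_f: float

    @property
    def e2(self) -> float:
        f = 1.0 / self.inv_f
        return f * (2.0 - f)

    @property
    def e(self) -> float:
        return math.sqrt(self.e2)


GRS80 = Ellipsoid(6378137.0, 298.257222101)
WGS84 = Ellipsoid(6378137.0, 298.257223563)


@dataclass(frozen=True)
class GeographicCRS:
    epsg: int
    name: str
    ellipsoid: Ellipsoid

    is_geographic = True
    unit_to_m = None  # degrees have no linear unit


@dataclass(frozen=True)
class LambertConformalConic:
    """Lambert Conformal Conic, two standard parallels (Snyder 15-4..15-11)."""

    epsg: int
    name: str
    ellipsoid: Ellipsoid
    lat0: float  # latitude of false origin, degrees
    lat1: float  # first standard parallel
    lat2: float  # second standard parallel
    lon0: float  # central meridian
    false_easting: float  # in native linear unit
    false_northing: float
    unit_to_m: float

    is_geographic = False

    def _constants(self):
        e = self.ellipsoid.e
        p0, p1, p2 = (math.radians(v) for v in (self.lat0, self.lat1, self.lat2))

        def m(phi):
            return math.cos(phi) / math.sqrt(1 - (e * math.sin(phi)) ** 2)

        def t(phi):
            es = e * math.sin(phi)
            return math.tan(math.pi / 4 - phi / 2) / ((1 - es) / (1 + es)) ** (e / 2)

        m1, m2 = m(p1), m(p2)
        t0, t1, t2 = t(p0), t(p1), t(p2)
        n = (math.log(m1) - math.log(m2)) / (math.log(t1) - math.log(t2))
        F = m1 / (n * t1 ** n)
        rho0 = self.ellipsoid.a * F * t0 ** n
        return e, n, F, rho0

    def forward(self, lon_deg: np.ndarray, lat_deg: np.ndarray):
        """Geographic degrees -> projected coordinates in the native unit."""
        e, n, F, rho0 = self._constants()
        a = self.ellipsoid.a
        phi = np.radians(lat_deg)
        es = e * np.sin(phi)
        t = np.tan(np.pi / 4 - phi / 2) / ((1 - es) / (1 + es)) ** (e / 2)
        rho = a * F * t ** n
        theta = n * np.radians(lon_deg - self.lon0)
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return (
            x / self.unit_to_m + self.false_easting,
            y / self.unit_to_m + self.false_northing,
        )

    def inverse(self, x: np.ndarray, y: np.ndarray):
        """Projected native-unit coordinates -> geographic degrees."""
        e, n, F, rho0 = self._constants()
        a = self.ellipsoid.a
        xm = (np.asarray(x, dtype=float) - self.false_easting) * self.unit_to_m
        ym = (np.asarray(y, dtype=float) - self.false_northing) * self.unit_to_m
        rho = np.copysign(np.hypot(xm, rho0 - ym), n)
        t = (rho / (a * F)) ** (1.0 / n)
        theta = np.arctan2(np.sign(n) * xm, np.sign(n) * (rho0 - ym))
        lon = np.degrees(theta / n) + self.lon0
        # fixed-point iteration for the conformal latitude inversion
        phi = np.pi / 2 - 2 * np.arctan(t)
        for _ in range(12):
            es = e * np.sin(phi)
            phi = np.pi / 2 - 2 * np.arctan(t * ((1 - es) / (1 + es)) ** (e / 2))
        return lon, np.degrees(phi)


_NC_LCC = dict(
    ellipsoid=GRS80,
    lat0=33.75,
    lat1=34.0 + 20.0 / 60.0,
    lat2=36.0 + 10.0 / 60.0,
    lon0=-79.0,
)

REGISTRY: dict[int, GeographicCRS | LambertConformalConic] = {
    4326: GeographicCRS(4326, "WGS 84", WGS84),
    4269: GeographicCRS(4269, "NAD83", GRS80),
    2264: LambertConformalConic(
        epsg=2264,
        name="NAD83 / North Carolina (ftUS)",
        false_easting=609601.2192024384 / US_SURVEY_FOOT_M,  # 2,000,000 ftUS
        false_northing=0.0,
        unit_to_m=US_SURVEY_FOOT_M,
        **_NC_LCC,
    ),
    32119: LambertConformalConic(
        epsg=32119,
        name="NAD83 / North Carolina (m)",
        false_easting=609601.22,
        false_northing=0.0,
        unit_to_m=1.0,
        **_NC_LCC,
    ),
}


def get_crs(epsg: int):
    try:
        return REGISTRY[int(epsg)]
    except (KeyError, TypeError, ValueError):
        raise CRSError(
            f"unknown EPSG code {epsg!r}; supported: {sorted(REGISTRY)}"
        ) from None


def is_geographic(epsg: int) -> bool:
    return get_crs(epsg).is_geographic


def unit_to_us_feet(epsg: int) -> float:
    """Conversion factor from the CRS linear unit to US survey feet."""
    crs = get_crs(epsg)
    if crs.is_geographic:
        raise CRSError(f"EPSG:{epsg} is geographic (degrees); no linear unit")
    return crs.unit_to_m / US_SURVEY_FOOT_M


def transform_coords(coords: np.ndarray, src_epsg: int, dst_epsg: int) -> np.ndarray:
    """Transform an (N, 2) coordinate array between registered CRSs."""
    coords = np.asarray(coords, dtype=float)
    if int(src_epsg) == int(dst_epsg):
        return coords.copy()
    src, dst = get_crs(src_epsg), get_crs(dst_epsg)
    x, y = coords[:, 0], coords[:, 1]
    if not src.is_geographic:
        lon, lat = src.inverse(x, y)
    else:
        lon, lat = x, y
    if not dst.is_geographic:
        ox, oy = dst.forward(lon, lat)
    else:
        ox, oy = lon, lat
    return np.column_stack([ox, oy])
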