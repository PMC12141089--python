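"""Equal-area map projection used to build the analysis grid.

Gridding occurrence data on unprojected latitude/longitude would make
northern cells physically smaller than southern ones (one degree of
longitude shrinks with the cosine of latitude), biasing any area-based
occupancy summary. All grid arithmetic therefore happens in an Albers
equal-area conic projection on the authalic sphere, the standard choice
for mid-latitude North American analyses. The projection is exposed as a
small immutable object with vectorized ``forward`` (lon/lat -> x/y metres)
and ``inverse`` transforms; its parameters are recorded in run metadata so
a grid is reproducible from its configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Authalic Earth radius in metres (sphere with the same surface area as
#: the WGS84 ellipsoid).
EARTH_RADIUS_M = 6_371_007.181


@dataclass(frozen=True)
class AlbersEqualArea:
    """Spherical Albers equal-area conic projection.

    Default parameters follow the conventional North America Albers
    setup: standard parallels 29.5 and 45.5 deg N, latitude of origin
    23 deg N, central meridian 96 deg W.

    Parameters
    ----------
    std_parallel_1, std_parallel_2
        Standard parallels in degrees; the cone is secant at these.
    lat_origin, lon_origin
        Origin of the projected coordinate system, degrees.
    radius_m
        Sphere radius in metres.
    """

    std_parallel_1: float = 29.5
    std_parallel_2: float = 45.5
    lat_origin: float = 23.0
    lon_origin: float = -96.0
    radius_m: float = EARTH_RADIUS_M

    def __post_init__(self) -> None:
        if not (-90.0 < self.std_parallel_1 < 90.0 and -90.0 < self.std_parallel_2 < 90.0):
            raise ValueError("standard parallels must lie strictly inside (-90, 90)")
        if self.radius_m <= 0:
            raise ValueError("radius_m must be positive")

    # Cone constant n and the C term of the spherical Albers formulas.
    @property
    def _n(self) -> float:
        p1, p2 = np.radians(self.std_parallel_1), np.radians(self.std_parallel_2)
        return float((np.sin(p1) + np.sin(p2)) / 2.0)

    @property
    def _c(self) -> float:
        p1 = np.radians(self.std_parallel_1)
        return float(np.cos(p1) ** 2 + 2.0 * self._n * np.sin(p1))

    @property
    def _rho0(self) -> float:
        phi0 = np.radians(self.lat_origin)
        return float(
            self.radius_m / self._n * np.sqrt(self._c - 2.0 * self._n * np.sin(phi0))
        )

    def forward(self, lon, lat):
        """Project geographic coordinates to planar metres.

        Parameters
        ----------
        lon, lat
            Scalars or arrays of WGS84 decimal degrees.

        Returns
        -------
        (x, y)
            Easting/northing in metres, same shape as the inputs.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
            raise ValueError("coordinates outside valid WGS84 range")
        n, c = self._n, self._c
        phi = np.radians(lat)
        theta = n * np.radians(lon - self.lon_origin)
        rho = self.radius_m / n * np.sqrt(c - 2.0 * n * np.sin(phi))
        x = rho * np.sin(theta)
        y = self._rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y):
        """Unproject planar metres back to (lon, lat) decimal degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n, c = self._n, self._c
        rho0y = self._rho0 - y
        rho = np.hypot(x, rho0y)
        # atan2 handles the southern cone (n < 0) sign convention.
        theta = np.arctan2(np.sign(n) * x, np.sign(n) * rho0y)
        sin_phi = (c - (rho * n / self.radius_m) ** 2) / (2.0 * n)
        phi = np.arcsin(np.clip(sin_phi, -1.0, 1.0))
        lon = self.lon_origin + np.degrees(theta / n)
        lat = np.degrees(phi)
        return lon, lat

    def to_dict(self) -> dict:
        """Serializable parameter record for run metadata."""
        return {
            "projection": "albers_equal_area_spherical",
            "std_parallel_1": self.std_parallel_1,
            "std_parallel_2": self.std_parallel_2,
            "lat_origin": self.lat_origin,
            "lon_origin": self.lon_origin,
            "radius_m": self.radius_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlbersEqualArea":
        keys = ("std_parallel_1", "std_parallel_2", "lat_origin", "lon_origin", "radius_m")
        return cls(**{k: d[k] for k in keys if k in d})
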