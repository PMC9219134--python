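"""Geographic ↔ planar coordinate conversion.

The Matérn kernel operates on Euclidean distance, so cluster coordinates
must live in a planar km system.  A single equirectangular projection about
the study-region centroid is used throughout: adequate at country scale,
trivially invertible, and dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


@dataclass(frozen=True)
class Projection:
    """Equirectangular projection centred at (lon0, lat0), output in km.

    x = R cos(lat0) (lon − lon0) π/180,  y = R (lat − lat0) π/180.
    """

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        k = np.pi / 180.0 * EARTH_RADIUS_KM
        x = k * np.cos(np.deg2rad(self.lat0)) * (lon - self.lon0)
        y = k * (lat - self.lat0)
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = np.pi / 180.0 * EARTH_RADIUS_KM
        lon = self.lon0 + x / (k * np.cos(np.deg2rad(self.lat0)))
        lat = self.lat0 + y / k
        return lon, lat

    @classmethod
    def centered_on(cls, lons, lats) -> "Projection":
        """Projection about the centroid of a point cloud."""
        return cls(lon0=float(np.mean(lons)), lat0=float(np.mean(lats)))
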