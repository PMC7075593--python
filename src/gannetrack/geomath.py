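"""Spherical-earth geometry helpers shared across the package.

All distances use a spherical Earth of radius 6371 km, which is well below
the ~200 km accuracy of threshold geolocation. The Lambert conformal conic
projection (spherical form) is used for kernel home-range estimation over
the NW Atlantic.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def great_circle_waypoints(lon1, lat1, lon2, lat2, n: int):
    """``n`` points interpolated along the great circle from start to end.

    Endpoints included; returns ``(lons, lats)`` arrays of length ``n``.
    """
    if n < 2:
        raise ValueError("need at least 2 waypoints")
    p1 = _unit(lon1, lat1)
    p2 = _unit(lon2, lat2)
    omega = np.arccos(np.clip(np.dot(p1, p2), -1.0, 1.0))
    f = np.linspace(0.0, 1.0, n)
    if omega < 1e-12:
        v = np.outer(np.ones(n), p1)
    else:
        v = (np.outer(np.sin((1 - f) * omega), p1) + np.outer(np.sin(f * omega), p2)) / np.sin(omega)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    lats = np.degrees(np.arcsin(v[:, 2]))
    lons = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    return lons, lats


def _unit(lon, lat):
    lam, phi = np.radians(lon), np.radians(lat)
    return np.array([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)])


class LambertConformalConic:
    """Spherical Lambert conformal conic projection, coordinates in km.

    Defaults cover the NW Atlantic with low distortion: standard parallels
    25°N / 45°N, origin 40°N, central meridian 75°W.
    """

    def __init__(self, lat1: float = 25.0, lat2: float = 45.0,
                 lat0: float = 40.0, lon0: float = -75.0):
        phi1, phi2, phi0 = np.radians([lat1, lat2, lat0])
        if abs(lat1 - lat2) < 1e-9:
            self.n = np.sin(phi1)
        else:
            self.n = (np.log(np.cos(phi1) / np.cos(phi2))
                      / np.log(np.tan(np.pi / 4 + phi2 / 2) / np.tan(np.pi / 4 + phi1 / 2)))
        self.F = np.cos(phi1) * np.tan(np.pi / 4 + phi1 / 2) ** self.n / self.n
        self.rho0 = EARTH_RADIUS_KM * self.F / np.tan(np.pi / 4 + phi0 / 2) ** self.n
        self.lon0 = lon0

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) km."""
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        rho = EARTH_RADIUS_KM * self.F / np.tan(np.pi / 4 + phi / 2) ** self.n
        x = rho * np.sin(self.n * lam)
        y = self.rho0 - rho * np.cos(self.n * lam)
        return x, y

    def inverse(self, x, y):
        """(x, y) km -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.sign(self.n) * np.hypot(x, self.rho0 - y)
        theta = np.arctan2(x, self.rho0 - y)
        phi = 2 * np.arctan((EARTH_RADIUS_KM * self.F / rho) ** (1.0 / self.n)) - np.pi / 2
        lam = theta / self.n
        return self.lon0 + np.degrees(lam), np.degrees(phi)
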