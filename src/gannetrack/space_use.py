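"""Winter range estimation and strategy assignment.

Positions are projected to planar km (spherical Lambert conformal conic,
standard parallels 25/45 N) and smoothed with an isotropic Gaussian kernel
whose bandwidth is chosen per individual by likelihood cross-validation
(maximising the leave-one-out predictive log-density). The 50% utilization
contour - the minimal-area region holding half the utilization mass - maps
"high use" winter range; the winter centroid is the mean position inside
the Dec 15 - Feb 15 window with t-based 95% CIs.

Wintering regions (box rules on the centroid):
GM   Gulf of Mexico          lon < -81 (west of Florida), 18 <= lat < 31
SE   southeast U.S. coast    lon >= -81, lat < 34
NE   northeast U.S. coast    34 <= lat <= 45 (North Carolina to Maine)
The source description "west of Florida (east of 81degW)" contradicts
itself; west of 81 W is what matches the geography and is used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist
from shapely.geometry import Polygon
from skimage import measure

from .geomath import LambertConformalConic

__all__ = [
    "select_bandwidth_lcv", "kde_grid", "kde_50_contour", "KernelRange",
    "winter_centroid", "assign_region", "WinterAssignment", "DEFAULT_PROJECTION",
]

DEFAULT_PROJECTION = LambertConformalConic()
WINTER_WINDOW = ((12, 15), (2, 15))  # Dec 15 - Feb 15


@dataclass(frozen=True)
class KernelRange:
    bandwidth_km: float
    contour_level: float
    density_threshold: float
    mass_inside: float
    polygons_km: list = field(repr=False)    # shapely polygons, projected km
    polygons_lonlat: list = field(repr=False)
    grid_x: np.ndarray = field(repr=False)
    grid_y: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)  # integrates to 1 over the grid


@dataclass(frozen=True)
class WinterAssignment:
    individual_id: str
    lon: float
    lat: float
    lon_ci: tuple
    lat_ci: tuple
    region: str  # GM | SE | NE | unclassified


def _loo_log_likelihood(d2: np.ndarray, h: float) -> float:
    """Leave-one-out Gaussian-kernel log-likelihood from squared distances."""
    n = d2.shape[0]
    k = np.exp(-d2 / (2.0 * h * h)) / (2.0 * np.pi * h * h)
    np.fill_diagonal(k, 0.0)
    f = k.sum(axis=1) / (n - 1)
    if np.any(f <= 0):
        return -np.inf
    return float(np.log(f).sum())


def select_bandwidth_lcv(points_km: np.ndarray, h_bounds=(0.5, 2000.0),
                         n_grid: int = 60, fallback_fraction: float = 0.1) -> float:
    """Likelihood cross-validation bandwidth (km) for an (n, 2) point set.

    Coarse search on a log-spaced grid, refined by bounded scalar
    minimisation around the best grid point. Deterministic. Degenerate
    inputs (duplicate-only points, where LCV diverges) fall back to a
    reference bandwidth - ``fallback_fraction`` of the bounds' geometric
    mean - with a warning.
    """
    pts = np.asarray(points_km, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need an (n>=5, 2) array of projected points")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    off_diag = d2[~np.eye(len(pts), dtype=bool)]
    if np.all(off_diag == 0):
        h_ref = fallback_fraction * float(np.sqrt(h_bounds[0] * h_bounds[1]))
        warnings.warn("all points coincide; LCV is degenerate, using reference bandwidth",
                      stacklevel=2)
        return h_ref
    grid = np.geomspace(h_bounds[0], h_bounds[1], n_grid)
    ll = np.array([_loo_log_likelihood(d2, h) for h in grid])
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    res = minimize_scalar(lambda h: -_loo_log_likelihood(d2, h),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3 * grid[best]})
    return float(res.x)


def kde_grid(points_km: np.ndarray, h: float, pad_factor: float = 5.0,
             cell_km: float = 10.0):
    """Gaussian KDE evaluated on a regular grid padded 5h beyond extent
    (wide enough to close the utilization mass to ~1e-6).

    The grid refines automatically when the cell is coarser than h/2.
    Returns (x, y, density) with density integrating to ~1 over the grid.
    """
    pts = np.asarray(points_km, dtype=float)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    cell = min(cell_km, h / 2.0)
    pad = pad_factor * h
    x = np.arange(pts[:, 0].min() - pad, pts[:, 0].max() + pad + cell, cell)
    y = np.arange(pts[:, 1].min() - pad, pts[:, 1].max() + pad + cell, cell)
    xx, yy = np.meshgrid(x, y)
    dens = np.zeros_like(xx)
    inv = 1.0 / (2.0 * h * h)
    for px, py in pts:
        dens += np.exp(-((xx - px) ** 2 + (yy - py) ** 2) * inv)
    dens /= 2.0 * np.pi * h * h * len(pts)
    return x, y, dens


def kde_50_contour(points_km: np.ndarray, h: float, contour_level: float = 0.5,
                   cell_km: float = 10.0,
                   projection: LambertConformalConic = DEFAULT_PROJECTION) -> KernelRange:
    """Utilization-distribution contour of the kernel density estimate.

    The density threshold is where cumulative sorted cell mass reaches
    ``contour_level``; polygons are traced at that level on the grid and
    returned both in projected km and back-transformed to lon/lat.
    """
    x, y, dens = kde_grid(points_km, h, cell_km=cell_km)
    cell = (x[1] - x[0]) * (y[1] - y[0])
    mass = dens * cell
    order = np.argsort(dens.ravel())[::-1]
    cum = np.cumsum(mass.ravel()[order])
    k = int(np.searchsorted(cum, contour_level))
    threshold = float(dens.ravel()[order[min(k, order.size - 1)]])
    inside = float(mass[dens >= threshold].sum())

    polys_km, polys_ll = [], []
    for contour in measure.find_contours(dens, threshold):
        cx = np.interp(contour[:, 1], np.arange(len(x)), x)
        cy = np.interp(contour[:, 0], np.arange(len(y)), y)
        if len(cx) < 4:
            continue
        poly = Polygon(np.column_stack([cx, cy]))
        if not poly.is_valid or poly.area == 0:
            continue
        polys_km.append(poly)
        lon, lat = projection.inverse(cx, cy)
        polys_ll.append(Polygon(np.column_stack([lon, lat])))
    return KernelRange(bandwidth_km=h, contour_level=contour_level,
                       density_threshold=threshold, mass_inside=inside,
                       polygons_km=polys_km, polygons_lonlat=polys_ll,
                       grid_x=x, grid_y=y, density=dens)


def _in_winter_window(times: pd.DatetimeIndex) -> np.ndarray:
    (m0, d0), (m1, d1) = WINTER_WINDOW
    md = np.asarray(times.month) * 100 + np.asarray(times.day)
    return (md >= m0 * 100 + d0) | (md <= m1 * 100 + d1)


def winter_centroid(track: pd.DataFrame, individual_id: str = "",
                    level: float = 0.95, min_positions: int = 3):
    """Mean winter (Dec 15 - Feb 15) position with t-based CIs per axis.

    Uses kept fixes only when a ``kept`` column is present. Raises
    ValueError("insufficient data...") below ``min_positions`` fixes.
    """
    df = track.copy()
    if "kept" in df.columns:
        df = df[df["kept"]]
    times = pd.DatetimeIndex(pd.to_datetime(df["time"]))
    df = df[_in_winter_window(times)]
    df = df.dropna(subset=["lon", "lat"])
    n = len(df)
    if n < min_positions:
        raise ValueError(f"insufficient data: {n} winter positions (need >= {min_positions})")
    out = {}
    for axis in ("lon", "lat"):
        vals = df[axis].to_numpy(float)
        m = float(vals.mean())
        if n > 1 and vals.std(ddof=1) > 0:
            half = float(t_dist.ppf(0.5 + level / 2, n - 1) * vals.std(ddof=1) / np.sqrt(n))
        else:
            half = 0.0
        out[axis] = (m, (m - half, m + half))
    region = assign_region(out["lon"][0], out["lat"][0])
    return WinterAssignment(individual_id=individual_id,
                            lon=out["lon"][0], lat=out["lat"][0],
                            lon_ci=out["lon"][1], lat_ci=out["lat"][1],
                            region=region)


def assign_region(lon: float, lat: float) -> str:
    """GM / SE / NE box assignment of a winter centroid (see module docs)."""
    if lon < -81.0 and 18.0 <= lat < 31.0:
        return "GM"
    if lon >= -81.0 and lat < 34.0 and lat >= 20.0:
        return "SE"
    if 34.0 <= lat <= 45.0:
        return "NE"
    return "unclassified"
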