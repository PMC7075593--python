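"""Coarse built-in land mask of eastern North America.

A single hand-digitised polygon (~50 vertices) approximating the Atlantic
and Gulf of Mexico coastline from the Gulf of St Lawrence to the Yucatan,
closed far inland to the west. It exists only to support the ">200 km
inland" position filter and the at-sea constraint of the synthetic
trajectory generator; it is NOT cartographic-quality (Newfoundland and the
Caribbean islands are omitted, Nova Scotia is fused to the mainland).
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .geomath import haversine_km

# (lon, lat) along the coast, north to south, then closed inland.
_COAST = [
    (-66.5, 50.2),   # Quebec north shore, St Lawrence estuary
    (-67.5, 49.3),
    (-66.0, 48.8),   # Gaspe peninsula north side
    (-64.4, 49.0),   # Gaspe tip (colony sits just offshore to the SE)
    (-64.9, 48.2),   # Chaleur Bay
    (-64.6, 47.0),   # New Brunswick east coast
    (-63.8, 46.1),
    (-61.5, 45.7),   # Cape Breton (fused)
    (-59.9, 45.9),
    (-60.5, 45.3),
    (-63.0, 44.6),   # Nova Scotia south shore
    (-65.5, 43.5),   # Yarmouth
    (-66.2, 44.5),   # Bay of Fundy mouth
    (-67.2, 44.6),   # Maine
    (-69.0, 43.8),
    (-70.5, 43.1),
    (-70.8, 42.6),   # Massachusetts Bay
    (-70.3, 41.7),   # Cape Cod (clipped)
    (-71.5, 41.4),   # Rhode Island
    (-74.0, 40.5),   # New York
    (-74.2, 39.5),   # New Jersey
    (-75.0, 38.4),   # Delmarva
    (-75.7, 36.9),   # Chesapeake mouth
    (-75.5, 35.2),   # Cape Hatteras
    (-77.2, 34.5),
    (-78.5, 33.8),   # Cape Fear
    (-79.5, 33.0),   # South Carolina
    (-80.5, 32.2),   # Georgia
    (-81.2, 30.7),   # north Florida
    (-80.5, 28.5),   # Cape Canaveral
    (-80.1, 26.8),
    (-80.2, 25.4),   # Miami
    (-81.2, 25.2),   # Florida Bay
    (-81.7, 26.4),   # SW Florida
    (-82.7, 27.9),   # Tampa
    (-83.7, 29.7),   # Big Bend
    (-85.3, 29.7),   # Panama City
    (-87.3, 30.3),   # Pensacola
    (-89.2, 30.1),
    (-89.4, 29.0),   # Mississippi delta
    (-91.3, 29.5),   # Louisiana
    (-93.8, 29.7),
    (-95.1, 29.1),   # Texas
    (-97.2, 27.3),   # Corpus Christi
    (-97.6, 25.9),   # Rio Grande
    (-97.5, 23.5),   # Mexico
    (-96.3, 19.8),   # Veracruz
    (-94.5, 18.2),
    (-92.5, 18.6),   # Campeche
    (-90.5, 19.9),
    (-90.4, 21.0),   # NW Yucatan
    (-88.4, 21.5),
    (-86.8, 21.3),   # NE Yucatan
    # close the polygon inland (never approached by at-sea tracks)
    (-87.5, 15.0),
    (-105.0, 15.0),
    (-105.0, 55.0),
    (-66.5, 55.0),
]

LAND_POLYGON: Polygon = Polygon(_COAST)
_PREPARED = prep(LAND_POLYGON)

# coastline densified once for fast nearest-coast distance queries
_boundary = np.asarray(_COAST[: _COAST.index((-87.5, 15.0))], dtype=float)
_segments = []
for _a, _b in zip(_boundary[:-1], _boundary[1:]):
    _n = max(2, int(np.ceil(haversine_km(*_a, *_b) / 20.0)))
    _segments.append(np.column_stack([np.linspace(_a[0], _b[0], _n),
                                      np.linspace(_a[1], _b[1], _n)]))
COAST_POINTS = np.vstack(_segments)


def is_on_land(lon: float, lat: float) -> bool:
    return bool(_PREPARED.contains(Point(float(lon), float(lat))))


def distance_to_coast_km(lon, lat) -> np.ndarray:
    """Distance (km) to the nearest point of the digitised coastline."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    d = haversine_km(lon[:, None], lat[:, None], COAST_POINTS[None, :, 0], COAST_POINTS[None, :, 1])
    return d.min(axis=1)


def inland_distance_km(lon, lat) -> np.ndarray:
    """Distance inland from the coast; 0 for positions at sea."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    out = np.zeros(lon.shape, dtype=float)
    on_land = np.array([is_on_land(x, y) for x, y in zip(lon, lat)])
    if on_land.any():
        out[on_land] = distance_to_coast_km(lon[on_land], lat[on_land])
    return out
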