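"""Threshold light-level geolocation and the position filters.

Sunset and sunrise are the times the 10-min light series crosses a fixed
threshold (default 16 on the logger's arbitrary 0-64 scale) with a minimum
dark period (default 4 h) separating them. Longitude comes from the timing
of local apparent midday/midnight (equation-of-time corrected), latitude
from day length at the calibrated sun elevation angle, giving two positions
per day with ~200 km accuracy. Around the equinoxes day length carries no
latitude information; those fixes are flagged rather than guessed.

Filters (applied in order, all fixes retained with audit flags):
equinox window -> inland (>200 km from the coastline on the continent,
the birds being exclusively pelagic when not breeding) -> unrealistic
speed (>1,200 km per 24 h, pro-rated to the actual inter-fix interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import landmask
from .geomath import haversine_km
from .solar import sun_declination_eot, solar_elevation

__all__ = [
    "detect_twilights", "positions_from_twilights", "calibrate_sun_elevation",
    "filter_positions", "CalibrationResult", "equinox_dates",
    "latitude_from_day_length", "longitude_from_midpoint",
]

LIGHT_THRESHOLD = 16.0
MIN_DARK_H = 4.0
MAX_KM_PER_DAY = 1200.0
INLAND_KM = 200.0
EQUINOX_WINDOW_D = 15
CALIBRATION_BAND = (-9.0, 0.0)


@dataclass(frozen=True)
class CalibrationResult:
    sun_elevation: float
    per_twilight: np.ndarray

    def __post_init__(self):
        if not np.isfinite(self.sun_elevation):
            raise ValueError("calibrated sun elevation is not finite")


def detect_twilights(light: pd.DataFrame, threshold: float = LIGHT_THRESHOLD,
                     min_dark_h: float = MIN_DARK_H) -> pd.DataFrame:
    """Twilight events from a uniform 10-min light series.

    ``light`` has columns time, light. A sunset is a downward threshold
    crossing followed by at least ``min_dark_h`` below threshold before the
    next upward crossing (the paired sunrise); shorter dark spells (cloud,
    shading) are ignored. Crossing times are linearly interpolated between
    samples. Returns columns time, kind with alternating sunset/sunrise;
    empty for polar-day/night records with no qualifying crossings.
    """
    df = light.sort_values("time").reset_index(drop=True)
    t = pd.DatetimeIndex(pd.to_datetime(df["time"]))
    v = df["light"].to_numpy(float)
    above = v >= threshold
    idx = np.flatnonzero(above[:-1] != above[1:])
    crossings = []
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + (t[i + 1] - t[i]) * float(frac)
        crossings.append((tc, "down" if above[i] else "up"))
    events = []
    min_dark = pd.Timedelta(hours=min_dark_h)
    k = 0
    while k < len(crossings) - 1:
        tc, kind = crossings[k]
        if kind == "down":
            t_up, kind_up = crossings[k + 1]
            if kind_up == "up" and (t_up - tc) >= min_dark:
                events.append({"time": tc, "kind": "sunset"})
                events.append({"time": t_up, "kind": "sunrise"})
                k += 2
                continue
        k += 1
    return pd.DataFrame(events, columns=["time", "kind"])


def longitude_from_midpoint(t_mid: pd.Timestamp, source: str) -> float:
    """Longitude at which ``t_mid`` is local apparent noon or midnight."""
    _, eot = sun_declination_eot(t_mid)
    utc_h = (t_mid.hour + t_mid.minute / 60.0 + t_mid.second / 3600.0
             + t_mid.microsecond / 3.6e9)
    target = 12.0 if source == "noon" else 0.0
    lon = 15.0 * (target - utc_h - float(np.atleast_1d(eot)[0]) / 60.0)
    return float((lon + 180.0) % 360.0 - 180.0)


def latitude_from_day_length(day_length_h: float, t_mid: pd.Timestamp,
                             sun_elevation: float,
                             lat_bounds=(-70.0, 70.0), tol: float = 0.01):
    """Latitude whose modelled day length (at the given angle) matches.

    Returns NaN when no latitude in ``lat_bounds`` is consistent, or when
    the solution is ill-conditioned (a 4-min day-length perturbation - one
    sampling interval of timing error - moves it by more than
    ``condition_limit_deg``): the equinox degeneracy. The caller flags
    such fixes.
    """
    decl, _ = sun_declination_eot(t_mid)
    dr = np.radians(float(np.atleast_1d(decl)[0]))
    h0 = np.radians(sun_elevation)

    def solve(day_h):
        cos_ha_target = np.cos(np.radians(day_h / 2.0 * 15.0))

        def f(lat_deg):
            phi = np.radians(lat_deg)
            return ((np.sin(h0) - np.sin(phi) * np.sin(dr))
                    / (np.cos(phi) * np.cos(dr)) - cos_ha_target)

        lo, hi = lat_bounds
        flo, fhi = f(lo), f(hi)
        if not np.isfinite(flo) or not np.isfinite(fhi) or flo * fhi > 0:
            return float("nan")
        return float(brentq(f, lo, hi, xtol=tol))

    condition_limit_deg = 20.0
    lat = solve(day_length_h)
    lat_p = solve(day_length_h + 4.0 / 60.0)
    lat_m = solve(day_length_h - 4.0 / 60.0)
    if np.isnan(lat) or np.isnan(lat_p) or np.isnan(lat_m) \
            or abs(lat_p - lat_m) > condition_limit_deg:
        return float("nan")
    return lat


def positions_from_twilights(events: pd.DataFrame, sun_elevation: float) -> pd.DataFrame:
    """Twice-daily positions from alternating twilight events.

    Each sunrise->sunset pair yields a noon fix, each sunset->sunrise pair
    a midnight fix (day length = 24 h minus night length). Fixes whose day
    length is inconsistent with any latitude get ``flag_equinox`` and a NaN
    latitude. Columns: time, lon, lat, source, day_length_h, flag_equinox.
    """
    ev = events.sort_values("time").reset_index(drop=True)
    rows = []
    for k in range(len(ev) - 1):
        a, b = ev.iloc[k], ev.iloc[k + 1]
        if a["kind"] == b["kind"]:
            continue
        span_h = (b["time"] - a["time"]) / pd.Timedelta(hours=1)
        if span_h > 24.0:
            continue
        t_mid = a["time"] + (b["time"] - a["time"]) / 2
        if a["kind"] == "sunrise":
            source, day_length = "noon", span_h
        else:
            source, day_length = "midnight", 24.0 - span_h
        lon = longitude_from_midpoint(t_mid, source)
        lat = latitude_from_day_length(day_length, t_mid, sun_elevation)
        rows.append({
            "time": t_mid, "lon": lon, "lat": lat, "source": source,
            "day_length_h": day_length, "flag_equinox": bool(np.isnan(lat)),
        })
    return pd.DataFrame(rows, columns=["time", "lon", "lat", "source",
                                       "day_length_h", "flag_equinox"])


def calibrate_sun_elevation(light: pd.DataFrame, colony_lon: float, colony_lat: float,
                            window=None, threshold: float = LIGHT_THRESHOLD,
                            min_dark_h: float = MIN_DARK_H,
                            band=CALIBRATION_BAND) -> CalibrationResult:
    """Per-logger sun elevation angle from a ground-truthing period.

    For every twilight detected while the bird is at the known colony, the
    angle is the geometric solar elevation at the observed crossing time;
    the calibration is their median, applied uniformly to that logger's
    whole dataset. A median outside ``band`` raises a warning (suspect
    shading), not an error.
    """
    df = light.copy()
    df["time"] = pd.to_datetime(df["time"])
    if window is not None:
        t0, t1 = (pd.Timestamp(w) for w in window)
        df = df[(df["time"] >= t0) & (df["time"] <= t1)]
    if df.empty:
        raise ValueError("calibration window contains no light data")
    ev = detect_twilights(df, threshold=threshold, min_dark_h=min_dark_h)
    if ev.empty:
        raise ValueError("calibration window contains no twilights")
    angles = solar_elevation(pd.DatetimeIndex(ev["time"]), colony_lon, colony_lat)
    med = float(np.median(angles))
    if not band[0] <= med <= band[1]:
        warnings.warn(f"calibrated sun elevation {med:.2f} deg outside sanity band {band}",
                      stacklevel=2)
    return CalibrationResult(sun_elevation=med, per_twilight=np.asarray(angles))


def equinox_dates(years) -> list:
    """Approximate March/September equinox dates (UTC) for given years."""
    out = []
    for y in np.atleast_1d(years):
        out.append(pd.Timestamp(int(y), 3, 20))
        out.append(pd.Timestamp(int(y), 9, 22))
    return out


def filter_positions(track: pd.DataFrame,
                     equinox_window_d: int = EQUINOX_WINDOW_D,
                     max_km_per_day: float = MAX_KM_PER_DAY,
                     inland_km: float = INLAND_KM) -> pd.DataFrame:
    """Apply the equinox / inland / speed filters; keep everything, flagged.

    The speed check compares each candidate fix with the previous *kept*
    fix, scaling the limit to the actual interval (fixes are nominally 12 h
    apart). Deterministic and idempotent.
    """
    out = track.sort_values("time").reset_index(drop=True).copy()
    if out.empty:
        for c in ("flag_equinox", "flag_inland", "flag_speed", "kept"):
            out[c] = pd.Series(dtype=bool)
        return out
    t = pd.DatetimeIndex(out["time"])
    years = np.unique(np.concatenate([t.year, t.year + 1, t.year - 1]))
    win = pd.Timedelta(days=equinox_window_d)
    eq_flag = np.zeros(len(out), dtype=bool)
    for eq in equinox_dates(years):
        eq_flag |= np.abs(t - eq) <= win
    if "flag_equinox" in out.columns:  # keep upstream unsolvable-latitude flags
        eq_flag |= out["flag_equinox"].fillna(False).to_numpy(bool)
    eq_flag |= out["lat"].isna().to_numpy()
    out["flag_equinox"] = eq_flag

    inland = landmask.inland_distance_km(out["lon"].to_numpy(), out["lat"].fillna(0.0).to_numpy())
    out["flag_inland"] = ~eq_flag & (inland > inland_km)

    speed_flag = np.zeros(len(out), dtype=bool)
    prev = None
    for i in range(len(out)):
        if out["flag_equinox"].iat[i] or out["flag_inland"].iat[i]:
            continue
        if prev is not None:
            dt_d = (t[i] - t[prev]) / pd.Timedelta(days=1)
            dist = haversine_km(out["lon"].iat[prev], out["lat"].iat[prev],
                                out["lon"].iat[i], out["lat"].iat[i])
            if dt_d > 0 and dist > max_km_per_day * dt_d:
                speed_flag[i] = True
                continue
        prev = i
    out["flag_speed"] = speed_flag
    out["kept"] = ~(out["flag_equinox"] | out["flag_inland"] | out["flag_speed"])
    return out
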