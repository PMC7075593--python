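"""Solar geometry: declination, equation of time, elevation, event times.

Implements the NOAA solar-calculator algorithm (Meeus-derived truncated
series), accurate to well under a minute of event time for 1900-2100 at
non-polar latitudes. Atmospheric refraction is deliberately NOT applied:
in threshold geolocation the effective sun elevation angle is a calibrated
quantity that absorbs refraction, sensor response and shading, so the
geometric elevation is the right frame for both calibration and inversion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "sun_declination_eot",
    "solar_elevation",
    "solar_noon_utc",
    "solar_event_times",
    "NoSolarEvent",
]


class NoSolarEvent(Exception):
    """The sun does not cross the requested elevation on the given day."""


def _julian_century(times) -> np.ndarray:
    t = pd.to_datetime(times)
    ns = np.asarray(pd.DatetimeIndex(np.atleast_1d(t)).asi8, dtype=float)
    jd = ns / 86400e9 + 2440587.5
    return (jd - 2451545.0) / 36525.0


def sun_declination_eot(times):
    """Solar declination (degrees) and equation of time (minutes).

    ``times`` may be a scalar or array of UTC timestamps. Returns a pair of
    numpy arrays (scalars squeezed to 0-d arrays work transparently).
    """
    jc = _julian_century(times)
    l0 = np.mod(280.46646 + jc * (36000.76983 + jc * 0.0003032), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = np.radians(m)
    c = (np.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
         + np.sin(2 * mr) * (0.019993 - 0.000101 * jc)
         + np.sin(3 * mr) * 0.000289)
    true_long = l0 + c
    omega = np.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(omega)
    obliq_r = np.radians(obliq)
    decl = np.degrees(np.arcsin(np.sin(obliq_r) * np.sin(np.radians(app_long))))
    y = np.tan(obliq_r / 2.0) ** 2
    l0r = np.radians(l0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * l0r)
        - 2.0 * e * np.sin(mr)
        + 4.0 * e * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * e * e * np.sin(2 * mr)
    )
    return decl, eot


def solar_elevation(times, lon, lat):
    """Geometric solar elevation angle (degrees) at UTC ``times``.

    ``lon`` positive east, ``lat`` positive north; vectorised over times.
    """
    t = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(times)))
    decl, eot = sun_declination_eot(t)
    minutes = (t.hour * 60 + t.minute + t.second / 60.0 + t.microsecond / 6e7).to_numpy(float)
    tst = np.mod(minutes + eot + 4.0 * np.asarray(lon, dtype=float), 1440.0)
    ha = np.radians(tst / 4.0 - 180.0)
    phi = np.radians(np.asarray(lat, dtype=float))
    dr = np.radians(decl)
    sin_elev = np.sin(phi) * np.sin(dr) + np.cos(phi) * np.cos(dr) * np.cos(ha)
    elev = np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))
    return elev if np.ndim(times) or isinstance(times, (list, pd.DatetimeIndex, np.ndarray)) else float(elev[0])


def solar_noon_utc(date, lon) -> pd.Timestamp:
    """UTC time of local solar noon on ``date`` at longitude ``lon``."""
    d = pd.Timestamp(date).normalize()
    t = d + pd.Timedelta(hours=12)
    for _ in range(2):  # EoT varies slowly; two passes converge to <1 s
        _, eot = sun_declination_eot(t)
        minutes = 720.0 - 4.0 * float(lon) - float(np.atleast_1d(eot)[0])
        t = d + pd.Timedelta(minutes=minutes)
    return t


def solar_event_times(date, lon, lat, sun_elevation: float = 0.0):
    """UTC (sunrise, sunset) when the sun crosses ``sun_elevation`` degrees.

    Raises :class:`NoSolarEvent` when the sun never crosses that elevation
    on the given civil day (polar day/night relative to the angle).
    """
    noon = solar_noon_utc(date, lon)
    phi = np.radians(float(lat))
    h0 = np.radians(float(sun_elevation))

    def _half_day_hours(t_est):
        decl, _ = sun_declination_eot(t_est)
        dr = np.radians(float(np.atleast_1d(decl)[0]))
        cos_ha = (np.sin(h0) - np.sin(phi) * np.sin(dr)) / (np.cos(phi) * np.cos(dr))
        if cos_ha < -1.0 or cos_ha > 1.0:
            raise NoSolarEvent(
                f"sun does not reach {sun_elevation:.2f} deg at lat {lat:.2f} on {pd.Timestamp(date).date()}"
            )
        return np.degrees(np.arccos(cos_ha)) / 15.0

    sunrise, sunset = noon, noon
    for _ in range(3):  # refine with declination at the event itself
        sunrise = noon - pd.Timedelta(hours=_half_day_hours(sunrise))
        sunset = noon + pd.Timedelta(hours=_half_day_hours(sunset))
    return sunrise, sunset
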