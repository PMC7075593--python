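"""Threshold geolocation: twilight detection, inversion, calibration, filters."""

import numpy as np
import pandas as pd
import pytest

from conftest import square_wave_light
from gannetrack import geolocation, solar
from gannetrack.geomath import haversine_km


def synth_events(lon, lat, start, n_days, angle):
    """Noiseless twilight events from the forward solar model."""
    rows = []
    for d in pd.date_range(start, periods=n_days, freq="D"):
        sr, ss = solar.solar_event_times(d, lon, lat, angle)
        rows.append({"time": sr, "kind": "sunrise"})
        rows.append({"time": ss, "kind": "sunset"})
    return pd.DataFrame(rows).sort_values("time").reset_index(drop=True)


class TestDetectTwilights:
    def test_constant_light_yields_no_events(self):
        light = pd.DataFrame({
            "time": pd.date_range("2011-01-01", periods=288, freq="10min"),
            "light": 40.0})
        assert geolocation.detect_twilights(light).empty

    def test_square_wave_crossings_exact(self):
        ev = geolocation.detect_twilights(square_wave_light())
        sunsets = ev[ev["kind"] == "sunset"]["time"]
        sunrises = ev[ev["kind"] == "sunrise"]["time"]
        assert all(t.hour == 18 or (t.hour == 17 and t.minute >= 55) for t in sunsets)
        # threshold 16 between 0 and 40: crossing interpolated inside one interval
        for t in sunsets:
            assert abs((t - t.normalize() - pd.Timedelta(hours=18)) / pd.Timedelta(minutes=1)) <= 10
        for t in sunrises:
            assert abs((t - t.normalize() - pd.Timedelta(hours=6)) / pd.Timedelta(minutes=1)) <= 10

    def test_short_dark_spells_are_ignored(self):
        light = square_wave_light()
        # a 1-h artificial shading dip at midday must not create twilights
        dip = (light["time"].dt.hour == 12)
        light.loc[dip, "light"] = 0.0
        ev = geolocation.detect_twilights(light)
        assert len(ev) == len(geolocation.detect_twilights(square_wave_light()))

    def test_synthetic_light_times_match_solar_model(self, ne_dataset):
        # crossings of the rendered light curve at threshold 16 happen at the
        # -4 deg solar elevation the sensor model encodes, within 10 min
        ds = ne_dataset
        light = ds.light[ds.light["time"] < ds.light["time"].iloc[0] + pd.Timedelta(days=5)]
        ev = geolocation.detect_twilights(light)
        assert len(ev) >= 8
        for _, e in ev.iterrows():
            sr, ss = solar.solar_event_times(e["time"].normalize(), ds.colony_lon,
                                             ds.colony_lat, -4.0)
            expected = sr if e["kind"] == "sunrise" else ss
            assert abs((e["time"] - expected) / pd.Timedelta(minutes=1)) < 10


class TestPositions:
    def test_noiseless_inversion_recovers_position(self):
        ev = synth_events(-60.0, 45.0, "2011-01-10", 8, -4.0)
        pos = geolocation.positions_from_twilights(ev, -4.0)
        good = pos[~pos["flag_equinox"]]
        assert len(good) >= 10
        assert np.abs(good["lon"] - (-60.0)).max() < 0.5
        assert np.abs(good["lat"] - 45.0).max() < 2.0

    def test_four_minute_shift_moves_longitude_one_degree(self):
        ev = synth_events(-60.0, 45.0, "2011-01-10", 4, -4.0)
        shifted = ev.assign(time=ev["time"] + pd.Timedelta(minutes=4))
        lon0 = geolocation.positions_from_twilights(ev, -4.0)["lon"].mean()
        lon1 = geolocation.positions_from_twilights(shifted, -4.0)["lon"].mean()
        assert lon1 - lon0 == pytest.approx(-1.0, abs=0.02)

    def test_longitude_independent_of_latitude(self):
        # perturbing true latitude changes day length but not midpoint timing
        ev45 = synth_events(-60.0, 45.0, "2011-01-10", 4, -4.0)
        ev35 = synth_events(-60.0, 35.0, "2011-01-10", 4, -4.0)
        lon45 = geolocation.positions_from_twilights(ev45, -4.0)["lon"]
        lon35 = geolocation.positions_from_twilights(ev35, -4.0)["lon"]
        assert np.abs(lon45.to_numpy() - lon35.to_numpy()).max() < 0.05

    def test_equinoctial_day_length_flags_latitude(self):
        # exactly 12 h of daylight at angle 0 carries no latitude information
        t0 = pd.Timestamp("2011-03-20 06:00")
        ev = pd.DataFrame({"time": [t0, t0 + pd.Timedelta(hours=12)],
                           "kind": ["sunrise", "sunset"]})
        pos = geolocation.positions_from_twilights(ev, 0.0)
        assert bool(pos["flag_equinox"].iloc[0])
        assert np.isnan(pos["lat"].iloc[0])


class TestCalibration:
    def test_recovers_rendered_sun_elevation(self, ne_track):
        calib, _ = ne_track
        # the light sensor model places threshold 16 at -4.0 deg elevation
        assert calib.sun_elevation == pytest.approx(-4.0, abs=0.3)
        assert -6.0 <= calib.sun_elevation <= -3.0  # the field band

    def test_empty_window_raises(self, ne_dataset):
        with pytest.raises(ValueError):
            geolocation.calibrate_sun_elevation(
                ne_dataset.light, -64.15, 48.5,
                window=("1990-01-01", "1990-01-02"))


class TestFilters:
    def test_speed_filter_pro_rata(self):
        # 1,300 km in 24 h violates the 1,200 km d^-1 ceiling
        t0 = pd.Timestamp("2011-01-10 12:00")
        lat = 40.0
        dlon = 1300.0 / (111.32 * np.cos(np.radians(lat)))
        track = pd.DataFrame({
            "time": [t0, t0 + pd.Timedelta(days=1), t0 + pd.Timedelta(days=2)],
            "lon": [-60.0, -60.0 + dlon, -60.0],
            "lat": [lat, lat, lat]})
        out = geolocation.filter_positions(track)
        assert not out["flag_speed"].iloc[0]
        assert out["flag_speed"].iloc[1]
        assert out["kept"].iloc[2]  # compared against the previous KEPT fix

    def test_inland_filter_threshold(self):
        track = pd.DataFrame({
            "time": pd.date_range("2011-01-10", periods=3, freq="12h"),
            "lon": [-83.0, -80.5, -70.0],
            "lat": [33.0, 33.5, 38.0]})
        out = geolocation.filter_positions(track)
        assert out["flag_inland"].iloc[0]       # ~250 km inland
        assert not out["flag_inland"].iloc[1]   # ~105 km inland: kept
        assert not out["flag_inland"].iloc[2]   # open ocean

    def test_equinox_window_flagging(self):
        track = pd.DataFrame({
            "time": [pd.Timestamp("2011-03-25"), pd.Timestamp("2011-05-01"),
                     pd.Timestamp("2011-09-15")],
            "lon": [-60.0, -60.0, -60.0], "lat": [40.0, 40.0, 40.0]})
        out = geolocation.filter_positions(track)
        assert list(out["flag_equinox"]) == [True, False, True]

    def test_empty_track(self):
        out = geolocation.filter_positions(pd.DataFrame(columns=["time", "lon", "lat"]))
        assert out.empty and "kept" in out.columns

    def test_filter_idempotence(self, ne_track):
        _, track = ne_track
        again = geolocation.filter_positions(track)
        pd.testing.assert_series_equal(track["kept"].reset_index(drop=True),
                                       again["kept"].reset_index(drop=True))


def test_round_trip_median_error_under_200km(ne_dataset, ne_track):
    _, track = ne_track
    kept = track[track["kept"]].copy()
    kept["date"] = pd.to_datetime(kept["time"]).dt.floor("D")
    truth = ne_dataset.truth_positions.set_index("date")
    m = kept.merge(truth, left_on="date", right_index=True, suffixes=("", "_true"))
    err = haversine_km(m["lon"], m["lat"], m["lon_true"], m["lat_true"])
    assert np.median(err) < 200.0


def test_error_grows_monotonically_with_shading_noise():
    from gannetrack import synthetic
    medians = []
    for sd in (0.0, 0.4, 1.2):
        ds = synthetic.simulate_individual(synthetic.DEFAULT_STRATEGIES["NE"], 2010,
                                           seed=9, shading_sd=sd)
        t0 = ds.light["time"].iloc[0]
        calib = geolocation.calibrate_sun_elevation(
            ds.light, ds.colony_lon, ds.colony_lat,
            window=(t0, t0 + pd.Timedelta(days=30)))
        ev = geolocation.detect_twilights(ds.light)
        track = geolocation.filter_positions(
            geolocation.positions_from_twilights(ev, calib.sun_elevation))
        kept = track[track["kept"]].copy()
        kept["date"] = pd.to_datetime(kept["time"]).dt.floor("D")
        truth = ds.truth_positions.set_index("date")
        m = kept.merge(truth, left_on="date", right_index=True, suffixes=("", "_true"))
        medians.append(np.median(haversine_km(m["lon"], m["lat"],
                                              m["lon_true"], m["lat_true"])))
    assert medians[0] < medians[1] < medians[2]
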