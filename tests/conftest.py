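import numpy as np
import pandas as pd
import pytest

from gannetrack import geolocation, synthetic


@pytest.fixture(scope="session")
def ne_dataset():
    """One noiseless NE individual; shared across geolocation/activity tests."""
    return synthetic.simulate_individual(synthetic.DEFAULT_STRATEGIES["NE"], 2010,
                                         seed=7, shading_sd=0.0)


@pytest.fixture(scope="session")
def ne_track(ne_dataset):
    """Calibrated, filtered geolocation track for the shared individual."""
    ds = ne_dataset
    t0 = ds.light["time"].iloc[0]
    calib = geolocation.calibrate_sun_elevation(
        ds.light, ds.colony_lon, ds.colony_lat,
        window=(t0, t0 + pd.Timedelta(days=30)))
    events = geolocation.detect_twilights(ds.light)
    raw = geolocation.positions_from_twilights(events, calib.sun_elevation)
    return calib, geolocation.filter_positions(raw)


def square_wave_light(n_days=3, dark_start_h=18, dark_end_h=6, high=40.0, low=0.0):
    """Light series dark between dark_start and dark_end UTC each day."""
    times = pd.date_range("2011-01-10", periods=n_days * 144, freq="10min")
    hours = times.hour + times.minute / 60.0
    dark = (hours >= dark_start_h) | (hours < dark_end_h)
    return pd.DataFrame({"time": times, "light": np.where(dark, low, high)})
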