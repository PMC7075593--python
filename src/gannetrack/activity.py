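"""Wet/dry activity budgets, flight bouts, daily SST and phenology.

The immersion channel is a per-10-minute count in [0, 200]: the number of
3-second wet samples in the interval, so ``count/200 * 10`` is wet minutes.
Days are UTC civil days (the logger clock); wet + dry hours equal the data
coverage of the day exactly (24 h when complete).

Phenology follows the 12-h dry-time rule: colony departure is the first
date with dry time < 12 h that starts a persistent run, and colony arrival
(next breeding onset) the first date back above 12 h. A persistence window
of N days (default 3) guards against single anomalous days; N=1 is the
literal rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "daily_budget", "detect_bouts", "daily_sst", "phenology_dates",
    "segment_seasons", "SeasonBounds", "PhenologyNotFound",
]

INTERVAL_MIN = 10.0
FULL_WET = 200


class PhenologyNotFound(Exception):
    """No date satisfies the phenology rule in the supplied series."""


@dataclass(frozen=True)
class SeasonBounds:
    """Annual-cycle segmentation of one individual's non-breeding period.

    The winter-site departure is never observed directly (the return leg
    overlaps the spring equinox, when latitude is unresolvable), so it is
    back-calculated from colony arrival assuming the spring transit takes
    as long as the fall transit.
    """
    colony_departure: pd.Timestamp
    winter_arrival: pd.Timestamp
    winter_departure: pd.Timestamp
    colony_arrival: pd.Timestamp

    def __post_init__(self):
        seq = [self.colony_departure, self.winter_arrival,
               self.winter_departure, self.colony_arrival]
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"season bounds out of order: {[str(s.date()) for s in seq]}")

    @property
    def durations(self) -> dict:
        return {
            "fall_migration": int((self.winter_arrival - self.colony_departure).days),
            "winter": int((self.winter_departure - self.winter_arrival).days),
            "spring_migration": int((self.colony_arrival - self.winter_departure).days),
        }

    def season_of(self, dates) -> pd.Series:
        """Label dates with breeding / fall_migration / winter / spring_migration."""
        d = pd.Series(pd.to_datetime(dates))
        lab = pd.Series("breeding", index=d.index)
        lab[(d >= self.colony_departure) & (d < self.winter_arrival)] = "fall_migration"
        lab[(d >= self.winter_arrival) & (d < self.winter_departure)] = "winter"
        lab[(d >= self.winter_departure) & (d < self.colony_arrival)] = "spring_migration"
        return lab


def _validate_immersion(immersion: pd.DataFrame) -> pd.DataFrame:
    df = immersion.copy()
    df["time"] = pd.to_datetime(df["time"])
    bad = df[(df["count"] < 0) | (df["count"] > FULL_WET)]
    if not bad.empty:
        first = bad.iloc[0]
        raise ValueError(
            f"immersion count out of [0, {FULL_WET}] at {first['time']} (count={first['count']})"
        )
    return df


def daily_budget(immersion: pd.DataFrame) -> pd.DataFrame:
    """Daily wet/dry hours from the immersion stream.

    ``immersion`` has columns time (UTC, 10-min grid) and count. Returns a
    frame indexed by date with wet_h, dry_h, coverage (fraction of the 144
    intervals present) and complete (coverage == 1).
    """
    df = _validate_immersion(immersion)
    date = df["time"].dt.floor("D")
    wet_min = df["count"].astype(float) / FULL_WET * INTERVAL_MIN
    g = pd.DataFrame({"date": date, "wet_min": wet_min}).groupby("date")
    out = g.agg(wet_min=("wet_min", "sum"), n=("wet_min", "size"))
    out["wet_h"] = out["wet_min"] / 60.0
    out["dry_h"] = out["n"] * INTERVAL_MIN / 60.0 - out["wet_h"]
    out["coverage"] = out["n"] / (24 * 60 / INTERVAL_MIN)
    out["complete"] = out["coverage"] >= 1.0
    return out.drop(columns=["wet_min", "n"]).reset_index().rename(columns={"date": "date"})


def detect_bouts(immersion: pd.DataFrame) -> pd.DataFrame:
    """Flight (dry) bouts from the immersion stream.

    A bout is a maximal run of consecutive intervals with count < 200,
    bounded by fully wet intervals (or the record ends); its duration is
    the summed dry minutes inside the run. Sub-interval timing is not
    recorded by the logger, so this is the finest resolvable definition.
    Bouts are assigned to the day containing their midpoint.
    """
    df = _validate_immersion(immersion).sort_values("time").reset_index(drop=True)
    dry = (df["count"] < FULL_WET).to_numpy()
    if not dry.any():
        return pd.DataFrame(columns=["start", "end", "dry_min", "date"])
    edges = np.diff(np.concatenate([[0], dry.view(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # exclusive
    dry_min = df["count"].astype(float).to_numpy()
    dry_min = (FULL_WET - dry_min) / FULL_WET * INTERVAL_MIN
    rows = []
    for s, e in zip(starts, ends):
        t0 = df["time"].iloc[s]
        t1 = df["time"].iloc[e - 1] + pd.Timedelta(minutes=INTERVAL_MIN)
        rows.append({
            "start": t0,
            "end": t1,
            "dry_min": float(dry_min[s:e].sum()),
            "date": (t0 + (t1 - t0) / 2).floor("D"),
        })
    return pd.DataFrame(rows)


def bout_stats(bouts: pd.DataFrame) -> pd.DataFrame:
    """Per-day bout count and mean bout duration (minutes)."""
    if bouts.empty:
        return pd.DataFrame(columns=["date", "n_bouts", "mean_bout_min"])
    g = bouts.groupby("date")["dry_min"]
    out = g.agg(n_bouts="size", mean_bout_min="mean").reset_index()
    return out


def daily_sst(temperature: pd.DataFrame) -> pd.DataFrame:
    """Daily mean +/- sample SD of wet-triggered temperature readings.

    Days with no readings are simply absent from the output; a single
    reading yields SD = NaN (sample SD undefined), by convention.
    """
    df = temperature.copy()
    df["time"] = pd.to_datetime(df["time"])
    df["date"] = df["time"].dt.floor("D")
    g = df.groupby("date")["temp_c"]
    out = g.agg(sst_mean="mean", sst_sd=lambda s: s.std(ddof=1), n_readings="size")
    return out.reset_index()


def _first_persistent(mask: pd.Series, n: int):
    """Index label of the first True that starts a run of >= n Trues."""
    arr = mask.to_numpy()
    run = 0
    for i in range(len(arr) - 1, -1, -1):
        run = run + 1 if arr[i] else 0
        arr[i] = run >= n  # reuse as "starts a long-enough run"
    hits = np.flatnonzero(arr)
    return None if hits.size == 0 else mask.index[hits[0]]


def phenology_dates(daily: pd.DataFrame, threshold_h: float = 12.0,
                    persistence_d: int = 3):
    """Colony departure and arrival dates from the 12-h dry-time rule.

    ``daily`` needs columns date and dry_h spanning breeding -> non-breeding
    -> breeding. Returns (departure, arrival) timestamps.
    """
    df = daily.sort_values("date").set_index("date")
    below = df["dry_h"] < threshold_h
    departure = _first_persistent(below.copy(), persistence_d)
    if departure is None:
        raise PhenologyNotFound(f"no persistent run of dry time < {threshold_h} h")
    after = df.loc[df.index > departure]
    above = after["dry_h"] > threshold_h
    arrival = _first_persistent(above.copy(), persistence_d)
    if arrival is None:
        raise PhenologyNotFound(f"no persistent run of dry time > {threshold_h} h after departure")
    return pd.Timestamp(departure), pd.Timestamp(arrival)


def segment_seasons(colony_departure, colony_arrival, winter_arrival) -> SeasonBounds:
    """Four-season segmentation given the three observable dates.

    Fall transit = departure -> winter arrival; the winter-site departure is
    colony arrival minus the fall-transit duration (equal-transit-time
    assumption); winter is the remainder in between.
    """
    dep = pd.Timestamp(colony_departure)
    arr = pd.Timestamp(colony_arrival)
    win = pd.Timestamp(winter_arrival)
    fall = win - dep
    if fall < pd.Timedelta(0):
        raise ValueError(f"winter arrival {win.date()} precedes colony departure {dep.date()}")
    winter_departure = arr - fall
    return SeasonBounds(colony_departure=dep, winter_arrival=win,
                        winter_departure=winter_departure, colony_arrival=arr)
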