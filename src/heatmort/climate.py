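"""Heat exposure metrics: NOAA heat index, city-level hourly medians,
daily means, and exposure-duration thresholds/indicators.

The city series is built the way Rio's heat monitoring does it: the heat
index is computed per station-hour, the hourly median across available
stations is taken (robust to single-station extremes), and daily values
are means of the hourly medians.  Exposure duration is measured as the
number of hours per day the hourly heat index spends above its own 90th /
95th / 97.5th quantile; a day is flagged "high" when that count exceeds
the 90th percentile of the count's own distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "heat_index",
    "city_hourly_median",
    "daily_metrics",
    "ThresholdSet",
    "fit_thresholds",
    "hours_above",
    "duration_indicator",
    "daily_exposure_table",
    "read_station_csv",
]

STATION_COLUMNS = ["datetime", "station_id", "temp_c", "rh_pct"]


# ---------------------------------------------------------------------------
# heat index (NOAA operational formulation)
# ---------------------------------------------------------------------------

def heat_index(temp_c, rh_pct):
    """NOAA operational heat index, in deg C.

    Evaluated internally in Fahrenheit: the simple Steadman-style formula
    ``0.5 * [T + 61 + (T - 68) * 1.2 + RH * 0.094]`` is averaged with T; if
    that average reaches 80 F the Rothfusz regression replaces it, with the
    low-RH adjustment (RH < 13 %, 80-112 F) subtracted and the high-RH
    adjustment (RH > 85 %, 80-87 F) added.  Accepts scalars or arrays.
    """
    t_c = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):  # NaN compares False, passes through
        raise ValueError("relative humidity must be within [0, 100] %")

    t = t_c * 9.0 / 5.0 + 32.0  # degF
    simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + rh * 0.094)
    hi = 0.5 * (simple + t)

    hot = hi >= 80.0
    if np.any(hot):
        tt, rr = t, rh
        roth = (-42.379 + 2.04901523 * tt + 10.14333127 * rr
                - 0.22475541 * tt * rr - 6.83783e-3 * tt ** 2
                - 5.481717e-2 * rr ** 2 + 1.22874e-3 * tt ** 2 * rr
                + 8.5282e-4 * tt * rr ** 2 - 1.99e-6 * tt ** 2 * rr ** 2)
        low_rh = (rr < 13.0) & (tt >= 80.0) & (tt <= 112.0)
        adj_low = np.where(
            low_rh,
            (13.0 - rr) / 4.0 * np.sqrt(np.clip(17.0 - np.abs(tt - 95.0), 0.0, None) / 17.0),
            0.0,
        )
        high_rh = (rr > 85.0) & (tt >= 80.0) & (tt <= 87.0)
        adj_high = np.where(high_rh, (rr - 85.0) / 10.0 * (87.0 - tt) / 5.0, 0.0)
        hi = np.where(hot, roth - adj_low + adj_high, hi)

    out = (hi - 32.0) * 5.0 / 9.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# station aggregation
# ---------------------------------------------------------------------------

def read_station_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["datetime"])
    missing = set(STATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"station CSV missing columns: {sorted(missing)}")
    return df


def city_hourly_median(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse station-hours to a city-level hourly series.

    The heat index is computed per station first and the median across
    stations taken afterwards; the temperature median is taken over station
    temperatures directly.  Station-hours with temperature but missing
    humidity contribute to the T median only.  Hours with no reporting
    station are simply absent from the output.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["timestamp", "t_median_c", "hi_median_c", "n_stations_used"])
    df = records.copy()
    ok_hi = df["temp_c"].notna() & df["rh_pct"].notna()
    df["hi_c"] = np.nan
    df.loc[ok_hi, "hi_c"] = heat_index(df.loc[ok_hi, "temp_c"], df.loc[ok_hi, "rh_pct"])
    g = df.groupby("datetime")
    out = pd.DataFrame({
        "t_median_c": g["temp_c"].median(),
        "hi_median_c": g["hi_c"].median(),
        "n_stations_used": g["temp_c"].count(),
    })
    out = out[out["n_stations_used"] >= 1]
    return out.rename_axis("timestamp").reset_index()


def daily_metrics(city_hours: pd.DataFrame, min_hours: int = 18) -> pd.DataFrame:
    """Daily means of the hourly city medians.

    Days with fewer than ``min_hours`` available city-hours are kept in the
    output with NaN metrics and ``complete = False``.
    """
    df = city_hours.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    g = df.groupby("date")
    out = pd.DataFrame({
        "t_med": g["t_median_c"].mean(),
        "hi_med": g["hi_median_c"].mean(),
        "n_hours": g["t_median_c"].count(),
    })
    out["complete"] = out["n_hours"] >= min_hours
    out.loc[~out["complete"], ["t_med", "hi_med"]] = np.nan
    return out.reset_index()


# ---------------------------------------------------------------------------
# exposure-duration thresholds and indicators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSet:
    """Hourly heat-index quantile thresholds and the hour-count cutoffs.

    ``hi_hourly_q*`` are quantiles of the city hourly heat index (deg C);
    ``count_cut_q*`` are the 90th percentiles of the daily counts of hours
    above each, i.e. the "high exposure period" cutoffs.
    """

    hi_hourly_q90: float
    hi_hourly_q95: float
    hi_hourly_q975: float
    count_cut_q90: float
    count_cut_q95: float
    count_cut_q975: float

    def to_yaml(self, path) -> None:
        data = {k: float(v) for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ThresholdSet":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _daily_hours_above(city_hours: pd.DataFrame, hi_threshold: float) -> pd.Series:
    df = city_hours.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    above = df["hi_median_c"] > hi_threshold
    return above.groupby(df["date"]).sum().astype(int)


def fit_thresholds(city_hours: pd.DataFrame, count_quantile: float = 0.90) -> ThresholdSet:
    """Estimate the heat-index quantiles and hour-count cutoffs from history.

    Quantiles use linear interpolation between order statistics (the numpy
    default), fixed so persisted thresholds are reproducible.  Requires at
    least one year of hourly history.
    """
    hi = city_hours["hi_median_c"].dropna()
    ts = pd.to_datetime(city_hours["timestamp"])
    if len(hi) == 0 or (ts.max() - ts.min()) < pd.Timedelta(days=364):
        raise ValueError("need at least one year of hourly history to fit thresholds")
    q90, q95, q975 = np.quantile(hi, [0.90, 0.95, 0.975])
    cuts = []
    for q in (q90, q95, q975):
        counts = _daily_hours_above(city_hours, q)
        cuts.append(float(np.quantile(counts, count_quantile)))
    return ThresholdSet(q90, q95, q975, *cuts)


def hours_above(city_hours: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Per-day counts of hours with hourly HI above each quantile threshold."""
    out = pd.DataFrame({
        "hours_above_q90": _daily_hours_above(city_hours, thresholds.hi_hourly_q90),
        "hours_above_q95": _daily_hours_above(city_hours, thresholds.hi_hourly_q95),
        "hours_above_q975": _daily_hours_above(city_hours, thresholds.hi_hourly_q975),
    })
    return out.reset_index()


def duration_indicator(hours_count, count_cut):
    """1 iff the day's hour count is strictly above the cutoff, else 0
    (a count equal to the cutoff is a 'normal' exposure period)."""
    return (np.asarray(hours_count) > count_cut).astype(int)


def daily_exposure_table(city_hours: pd.DataFrame, thresholds: ThresholdSet,
                         min_hours: int = 18) -> pd.DataFrame:
    """Assemble the per-day exposure table: t_med, hi_med, hour counts and
    high/normal indicators for the three heat-index quantiles."""
    daily = daily_metrics(city_hours, min_hours=min_hours)
    counts = hours_above(city_hours, thresholds)
    out = daily.merge(counts, on="date", how="left")
    for q, cut in (("q90", thresholds.count_cut_q90),
                   ("q95", thresholds.count_cut_q95),
                   ("q975", thresholds.count_cut_q975)):
        col = f"hours_above_{q}"
        out[col] = out[col].fillna(0).astype(int)
        out[f"ind_{q}"] = duration_indicator(out[col], cut)
    return out
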