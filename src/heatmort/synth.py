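"""Synthetic weather and mortality generators with known ground truth.

The weather generator emulates a multi-station tropical (Southern
Hemisphere) hourly record: an annual temperature cycle peaking in mid
January, a diurnal cycle peaking mid afternoon, station-level offsets and
noise, humidity moving inversely to the diurnal temperature anomaly, and
missing-at-random station-hours.

The mortality generator draws daily death counts around a smooth
long-term trend, a two-peak annual cycle (first two Fourier harmonics),
and a day-of-week pattern, multiplied by a known exposure-lag-response
surface.  Counts are Poisson, or negative-binomial parameterized so that
variance = dispersion x mean when a variance-inflation factor above 1 is
requested.  Both generators are deterministic under a fixed seed, so the
true surface can be used for parameter-recovery tests downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeatherSimConfig",
    "MortalitySimConfig",
    "ExposureLagSurface",
    "null_surface",
    "linear_heat_surface",
    "indicator_surface",
    "generate_weather",
    "generate_deaths",
]

_ANNUAL_PEAK_DOY = 15.0   # mid-January: austral summer
_DIURNAL_PEAK_HOUR = 14.0


# ---------------------------------------------------------------------------
# exposure-lag-response ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureLagSurface:
    """Known log relative-risk surface over (exposure value, lag 0..max_lag).

    ``log_rr_fn(x, lag)`` must return 0 at the centering value for every
    lag, so the generated risk is a pure contrast against the center.
    """

    log_rr_fn: Callable[[np.ndarray, int], np.ndarray]
    centering_value: float
    max_lag: int = 10

    def cumulative_log_rr(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(self.log_rr_fn(x, lag) for lag in range(self.max_lag + 1))


def null_surface(centering_value: float = 0.0, max_lag: int = 10) -> ExposureLagSurface:
    """No exposure effect: log RR identically zero."""
    return ExposureLagSurface(lambda x, lag: np.zeros_like(np.asarray(x, dtype=float)),
                              centering_value, max_lag)


def linear_heat_surface(centering_value: float, reference_value: float,
                        cumulative_rr_at_reference: float,
                        max_lag: int = 10) -> ExposureLagSurface:
    """Log RR linear in exposure and constant across lags, calibrated so the
    cumulative (lags 0..max_lag) RR at ``reference_value`` equals
    ``cumulative_rr_at_reference``.  Lies inside the span of the natural
    spline x lag spline cross-basis, so an unbiased fit can recover it."""
    slope = np.log(cumulative_rr_at_reference) / (reference_value - centering_value)
    per_lag = slope / (max_lag + 1)

    def f(x, lag):
        return per_lag * (np.asarray(x, dtype=float) - centering_value)

    return ExposureLagSurface(f, centering_value, max_lag)


def indicator_surface(cumulative_rr: float, max_lag: int = 10) -> ExposureLagSurface:
    """Surface for a 0/1 duration indicator: log RR spread evenly over the
    lags, summing to log(cumulative_rr) on 'high' days."""
    per_lag = np.log(cumulative_rr) / (max_lag + 1)

    def f(x, lag):
        return per_lag * np.asarray(x, dtype=float)

    return ExposureLagSurface(f, centering_value=0.0, max_lag=max_lag)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeatherSimConfig:
    n_stations: int = 16
    start_date: str = "2012-01-01"
    end_date: str = "2024-06-30"
    annual_mean_temp: float = 24.2      # deg C, city-wide mean
    annual_amplitude: float = 3.5       # deg C half-range of the yearly cycle
    diurnal_amplitude: float = 3.0      # deg C half-range within a day
    humidity_mean: float = 75.0         # %
    humidity_amplitude: float = 15.0    # % swing opposing the diurnal cycle
    station_noise_sd: float = 1.0       # deg C station offset and hourly noise
    synoptic_sd: float = 2.0            # deg C day-to-day weather variability
    synoptic_rho: float = 0.75          # AR(1) persistence of daily anomalies
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.annual_amplitude, self.diurnal_amplitude, self.humidity_amplitude) < 0:
            raise ValueError("amplitudes must be non-negative")
        if pd.Timestamp(self.start_date) > pd.Timestamp(self.end_date):
            raise ValueError("start_date must not be after end_date")


def generate_weather(config: WeatherSimConfig) -> pd.DataFrame:
    """Hourly station records (datetime, station_id, temp_c, rh_pct).

    Temperature = annual cycle + diurnal cycle + station offset + noise;
    humidity = mean - amplitude x (diurnal anomaly / diurnal amplitude)
    + noise, clipped to [5, 100] %.  Missing station-hours are dropped
    uniformly at random at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    hours = pd.date_range(config.start_date,
                          pd.Timestamp(config.end_date) + pd.Timedelta(hours=23),
                          freq="h")
    n_h = len(hours)
    doy = hours.dayofyear.to_numpy(dtype=float)
    hod = hours.hour.to_numpy(dtype=float)

    annual = config.annual_amplitude * np.cos(2 * np.pi * (doy - _ANNUAL_PEAK_DOY) / 365.25)
    diurnal_shape = np.cos(2 * np.pi * (hod - _DIURNAL_PEAK_HOUR) / 24.0)
    diurnal = config.diurnal_amplitude * diurnal_shape

    # synoptic weather: AR(1) daily anomaly shared by all stations, so daily
    # means vary from day to day instead of tracking the seasonal cycle exactly
    n_days = (hours[-1].normalize() - hours[0].normalize()).days + 1
    innov = rng.normal(0.0, config.synoptic_sd * np.sqrt(1 - config.synoptic_rho ** 2), n_days)
    syn = np.empty(n_days)
    syn[0] = rng.normal(0.0, config.synoptic_sd)
    for d in range(1, n_days):
        syn[d] = config.synoptic_rho * syn[d - 1] + innov[d]
    day_index = ((hours - hours[0].normalize()).days).to_numpy()
    synoptic = syn[day_index]

    offsets = rng.normal(0.0, config.station_noise_sd, size=config.n_stations)
    frames = []
    for s in range(config.n_stations):
        noise = rng.normal(0.0, config.station_noise_sd, size=n_h)
        temp = config.annual_mean_temp + annual + synoptic + diurnal + offsets[s] + noise
        rh = (config.humidity_mean - config.humidity_amplitude * diurnal_shape
              + rng.normal(0.0, 3.0, size=n_h))
        rh = np.clip(rh, 5.0, 100.0)
        keep = rng.random(n_h) >= config.missing_rate
        frames.append(pd.DataFrame({
            "datetime": hours[keep],
            "station_id": f"S{s:02d}",
            "temp_c": np.round(temp[keep], 3),
            "rh_pct": np.round(rh[keep], 3),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["datetime", "station_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MortalitySimConfig:
    baseline_level: float = 30.0
    trend_coeffs: tuple[float, ...] = (0.05, -0.1)   # polynomial in scaled time
    season_coeffs: tuple[float, float, float, float] = (0.06, 0.0, 0.03, 0.0)
    dow_effects: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 0.97, 0.95)  # Mon..Sun
    true_surface: ExposureLagSurface = field(default_factory=null_surface)
    dispersion: float = 1.0
    code_pool: tuple[str, ...] = ("I219", "I10", "E149", "J189", "C349", "G309", "N390", "R99")
    p_elderly: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1")
        if len(self.dow_effects) != 7 or min(self.dow_effects) <= 0:
            raise ValueError("dow_effects must be 7 positive factors")


def expected_deaths(config: MortalitySimConfig, dates: pd.DatetimeIndex,
                    exposures: Sequence[tuple[pd.Series, ExposureLagSurface]]) -> np.ndarray:
    """Daily expected counts: baseline x trend x seasonality x day-of-week
    x exp(sum over lags of each surface's log RR).  Each exposure series
    must cover every date plus the preceding max_lag days."""
    n = len(dates)
    u = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
    log_mu = np.log(config.baseline_level) * np.ones(n)
    for i, c in enumerate(config.trend_coeffs):
        log_mu += c * u ** (i + 1)
    doy = dates.dayofyear.to_numpy(dtype=float)
    a1, b1, a2, b2 = config.season_coeffs
    ang = 2 * np.pi * doy / 365.25
    log_mu += a1 * np.cos(ang) + b1 * np.sin(ang) + a2 * np.cos(2 * ang) + b2 * np.sin(2 * ang)
    log_mu += np.log(np.asarray(config.dow_effects))[dates.dayofweek]

    for series, surface in exposures:
        x = series.reindex(pd.date_range(dates[0] - pd.Timedelta(days=surface.max_lag),
                                         dates[-1], freq="D"))
        if x.isna().any():
            raise ValueError("exposure series has gaps inside the simulation window")
        xv = x.to_numpy(dtype=float)
        L = surface.max_lag
        for lag in range(L + 1):
            log_mu += surface.log_rr_fn(xv[L - lag: len(xv) - lag], lag)
    return np.exp(log_mu)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 1.0:
        return rng.poisson(mu)
    # negative binomial with variance = dispersion * mean:
    # r = mu / (phi - 1), p = r / (r + mu) = 1 / phi
    r = mu / (dispersion - 1.0)
    return rng.negative_binomial(r, 1.0 / dispersion)


def generate_deaths(config: MortalitySimConfig,
                    exposures: Sequence[tuple[pd.Series, ExposureLagSurface]] | None = None,
                    start: str | None = None, end: str | None = None) -> pd.DataFrame:
    """Line-listed death records (date, icd10, age) over [start, end].

    The window defaults to the span of the first exposure series minus the
    lag run-in.  ICD codes are sampled uniformly from ``code_pool``; ages
    are uniform within 30-64 or 65-95 with P(65+) = ``p_elderly``.
    """
    exposures = list(exposures or [])
    if start is None or end is None:
        if not exposures:
            raise ValueError("either a date window or an exposure series is required")
        idx = exposures[0][0].index
        L = exposures[0][1].max_lag
        start = start or (idx[0] + pd.Timedelta(days=L))
        end = end or idx[-1]
    dates = pd.date_range(start, end, freq="D")

    rng = np.random.default_rng(config.seed)
    mu = expected_deaths(config, dates, exposures)
    counts = _draw_counts(rng, mu, config.dispersion)

    total = int(counts.sum())
    rec_dates = np.repeat(dates.to_numpy(), counts)
    codes = rng.choice(np.asarray(config.code_pool), size=total)
    elderly = rng.random(total) < config.p_elderly
    ages = np.where(elderly,
                    rng.integers(65, 96, size=total),
                    rng.integers(30, 65, size=total))
    return pd.DataFrame({"date": rec_dates, "icd10": codes, "age": ages})


def daily_counts(records: pd.DataFrame, start, end) -> pd.Series:
    """Zero-filled daily total counts from line-listed records."""
    window = pd.date_range(start, end, freq="D")
    c = records.groupby(pd.to_datetime(records["date"]).dt.normalize()).size()
    return c.reindex(window, fill_value=0).astype(int)
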