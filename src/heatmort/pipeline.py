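"""End-to-end orchestration: from station/death CSVs (or synthetic mode)
to exposure tables, cause series summaries, fitted DLNM variants, RR and
threshold tables, duration-indicator effects and AIC/qAIC comparisons.

Every constant of the analysis (lag length, knot placements, eligibility
cutoffs, exposure variants) lives in one RunConfig so that sensitivity
runs are config edits.  A run manifest (config + seed) is written next to
the outputs so each table can be regenerated from it alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate, mortality, synth
from .basis import CrossBasisSpec, NaturalSplineSpec, build_crossbasis, build_linear_lagged, default_lag_spec
from .inference import compare_models, find_first_risk, indicator_effect, predict_rr
from .regression import BaselineSpec, build_baseline_design, fit_glm

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "fit_exposure_model"]

INDICATOR_VARIANTS = ("ind_q90", "ind_q95", "ind_q975")


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from YAML."""

    output_dir: str = "out"
    stations_csv: str | None = None
    deaths_csv: str | None = None
    holidays: list[str] = field(default_factory=list)
    synthetic: bool = True
    start_date: str = "2018-01-01"
    end_date: str = "2022-12-31"
    age_cut: int = 65
    metrics: list[str] = field(default_factory=lambda: ["t_med", "hi_med"])
    indicators: list[str] = field(default_factory=lambda: list(INDICATOR_VARIANTS))
    max_lag: int = 10
    exposure_knot_quantiles: list[float] = field(default_factory=lambda: [0.10, 0.75, 0.90])
    lag_knots: list[float] = field(default_factory=lambda: [2.0, 5.0, 8.0])
    trend_knots: int = 6
    season_knots: int = 6
    min_hours: int = 18
    external_range: str = "printed"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def validate_inputs(stations_csv=None, deaths_csv=None) -> list[str]:
    """Schema / range / coverage checks; returns a list of problems (empty
    when the inputs are clean)."""
    problems: list[str] = []
    if stations_csv is not None:
        try:
            st = climate.read_station_csv(stations_csv)
        except Exception as e:  # noqa: BLE001 - report, not raise
            return [f"stations: {e}"]
        bad_rh = st[(st["rh_pct"] < 0) | (st["rh_pct"] > 100)]
        for i, row in bad_rh.iterrows():
            problems.append(f"stations row {i}: humidity {row['rh_pct']} outside [0, 100]")
        days = pd.to_datetime(st["datetime"]).dt.normalize().drop_duplicates().sort_values()
        gaps = days.diff().dt.days
        for d, g in zip(days[gaps > 1], gaps[gaps > 1]):
            problems.append(f"stations: gap of {int(g) - 1} day(s) before {d.date()}")
    if deaths_csv is not None:
        try:
            de = mortality.read_deaths_csv(deaths_csv)
        except Exception as e:  # noqa: BLE001
            return problems + [f"deaths: {e}"]
        for i, code in de["icd10"].items():
            try:
                mortality.normalize_icd(code)
            except ValueError:
                problems.append(f"deaths row {i}: malformed ICD-10 code {code!r}")
    return problems


def _exposure_spec(x: pd.Series, quantiles, lag_knots, max_lag, name) -> CrossBasisSpec:
    vals = x.dropna().to_numpy()
    knots = tuple(np.quantile(vals, quantiles))
    exp_spec = NaturalSplineSpec(interior_knots=knots,
                                 boundary_knots=(float(vals.min()), float(vals.max())),
                                 include_intercept=False)
    return CrossBasisSpec(exposure=exp_spec, lag=default_lag_spec(max_lag, lag_knots),
                          max_lag=max_lag, centering_value=float(vals.mean()), name=name)


def fit_exposure_model(y: pd.Series, exposure: pd.Series, cfg: RunConfig,
                       likelihood: str, indicator: pd.Series | None = None,
                       metric_name: str = "exp"):
    """Fit one model variant: baseline + smooth exposure cross-basis
    (+ optionally a duration-indicator cross-basis).  Returns
    (FitResult, smooth CrossBasisSpec, indicator CrossBasisSpec | None)."""
    dates = y.index
    spec = _exposure_spec(exposure, cfg.exposure_knot_quantiles, cfg.lag_knots,
                          cfg.max_lag, name=f"cb_{metric_name}")
    cbm = build_crossbasis(exposure.reindex(dates).to_numpy(), spec)
    base = build_baseline_design(dates, BaselineSpec(cfg.trend_knots, cfg.season_knots,
                                                     holiday_dates=tuple(cfg.holidays)))
    X = pd.concat([base.reset_index(drop=True),
                   pd.DataFrame(cbm.values, columns=cbm.names)], axis=1)
    valid = cbm.valid
    ind_spec = None
    if indicator is not None:
        lag_spec = default_lag_spec(cfg.max_lag, cfg.lag_knots)
        ibm = build_linear_lagged(indicator.reindex(dates).to_numpy(), lag_spec,
                                  max_lag=cfg.max_lag, name=f"ind_{metric_name}")
        X = pd.concat([X, pd.DataFrame(ibm.values, columns=ibm.names)], axis=1)
        valid = valid & ibm.valid
        ind_spec = ibm.spec
    fit = fit_glm(y.to_numpy()[valid], X.loc[valid], likelihood=likelihood)
    return fit, spec, ind_spec


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis and write the output bundle.

    Outputs under ``cfg.output_dir``: daily_exposure.csv, thresholds.yaml,
    series_summary.csv, rr_thresholds.csv (RR at Q75/Q90 and first-risk
    values per cause x metric), indicator_effects.csv, ic_comparison.csv
    and manifest.json.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = cfg.seed

    if cfg.synthetic:
        wcfg = synth.WeatherSimConfig(n_stations=6, start_date=cfg.start_date,
                                      end_date=cfg.end_date, seed=rng_seed)
        stations = synth.generate_weather(wcfg)
    else:
        stations = climate.read_station_csv(cfg.stations_csv)

    city = climate.city_hourly_median(stations)
    thresholds = climate.fit_thresholds(city)
    exposure = climate.daily_exposure_table(city, thresholds, min_hours=cfg.min_hours)
    exposure = exposure.set_index("date")
    exposure.to_csv(out / "daily_exposure.csv")
    thresholds.to_yaml(out / "thresholds.yaml")

    if cfg.synthetic:
        surface = synth.linear_heat_surface(
            centering_value=float(exposure["t_med"].mean()),
            reference_value=float(exposure["t_med"].quantile(0.90)),
            cumulative_rr_at_reference=1.12, max_lag=cfg.max_lag)
        mcfg = synth.MortalitySimConfig(baseline_level=30.0, dispersion=1.3, seed=rng_seed + 1)
        deaths = synth.generate_deaths(
            mcfg, [(exposure["t_med"].ffill(), surface)],
            start=exposure.index[cfg.max_lag], end=exposure.index[-1])
    else:
        deaths = mortality.read_deaths_csv(cfg.deaths_csv)

    win0 = exposure.index[cfg.max_lag]
    win1 = exposure.index[-1]
    series = mortality.build_series(deaths, win0, win1, age_cut=cfg.age_cut,
                                    external_range=cfg.external_range)
    summary = mortality.summary_table(series)
    summary.to_csv(out / "series_summary.csv", index=False)

    rr_rows, ind_rows, ic_rows, n_models = [], [], [], 0
    for (cause, band), s in series.items():
        if not s.eligible:
            continue
        y = s.daily_counts
        fits = {}
        for metric in cfg.metrics:
            x = exposure[metric].ffill().bfill()
            fit, spec, _ = fit_exposure_model(y, x, cfg, s.likelihood, metric_name=metric)
            fits[metric] = fit
            n_models += 1

            vals = x.reindex(y.index).to_numpy()
            grid = np.arange(spec.centering_value, float(np.nanmax(vals)) + 1e-9, 0.1)
            pred = predict_rr(fit, spec, grid)
            thr = find_first_risk(pred, exposure_values=vals)
            q75, q90 = np.nanquantile(vals, [0.75, 0.90])
            rr75, rr90 = pred.at(q75), pred.at(q90)
            rr_rows.append({
                "cause": cause, "age_group": band, "metric": metric,
                "risk_threshold": thr.label(),
                "rr_q75": rr75[0], "rr_q75_low": rr75[1], "rr_q75_high": rr75[2],
                "rr_q90": rr90[0], "rr_q90_low": rr90[1], "rr_q90_high": rr90[2],
            })

            for ind in cfg.indicators:
                fit_i, _, ind_spec = fit_exposure_model(
                    y, x, cfg, s.likelihood, indicator=exposure[ind], metric_name=metric)
                fits[f"{metric}+{ind}"] = fit_i
                n_models += 1
                rr, lo, hi = indicator_effect(fit_i, ind_spec)
                ind_rows.append({"cause": cause, "age_group": band, "metric": metric,
                                 "indicator": ind, "rr": rr, "rr_low": lo, "rr_high": hi})

        cmp_df = compare_models(fits)
        cmp_df.insert(0, "age_group", band)
        cmp_df.insert(0, "cause", cause)
        ic_rows.append(cmp_df)

    pd.DataFrame(rr_rows).to_csv(out / "rr_thresholds.csv", index=False)
    pd.DataFrame(ind_rows).to_csv(out / "indicator_effects.csv", index=False)
    if ic_rows:
        pd.concat(ic_rows, ignore_index=True).to_csv(out / "ic_comparison.csv", index=False)
    manifest = {"config": asdict(cfg), "seed": cfg.seed, "n_models": n_models,
                "window": [str(win0.date()), str(win1.date())]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
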