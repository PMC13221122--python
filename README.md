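# heatmort

Heat–mortality time-series analysis for a tropical city: heat-index
exposure metrics, exposure-*duration* indicators, and distributed lag
nonlinear models (DLNMs) for cause-specific daily death counts.

## The problem

Extreme heat raises short-term mortality, with the burden concentrated in
the elderly and in specific causes of death (cardiovascular, metabolic,
renal, dementia). Health departments that operate heat warning systems
need to know (a) at what temperature the risk becomes significant, (b)
over how many lag days the effect unfolds, and (c) whether *how long* a
day stays hot carries risk beyond its daily average — the trigger metric
used by Rio de Janeiro's heat protocol, which counts hours spent above
high heat-index thresholds.

This package implements that full analysis pipeline for daily count data,
together with a synthetic data generator with known ground truth so every
stage (exposure construction, series eligibility rules, model fitting,
relative-risk inference) can be validated by parameter recovery.

## The model

Daily deaths $Y_t$ for one cause group and age band follow a log-linear
count model

$$\log \mu_t = \alpha + s_{\text{trend}}(t) + s_{\text{doy}}(\text{doy}_t)
  + \gamma_{\text{dow}(t)} + \sum_{j,\ell} \beta_{j\ell}\, w_{j\ell,t},$$

with $Y_t \sim$ Poisson (or quasipoisson when the series' variance/mean
ratio exceeds 1.6). $s_{\text{trend}}$ is a natural cubic spline over the
study window (6 knots), $s_{\text{doy}}$ a cyclic cubic spline over
day-of-year (6 knots, period 366, allowing the two yearly mortality
peaks), and dow a day-of-week factor with holidays recoded to Sunday.

The exposure enters through a DLNM cross-basis over lags 0–10:

$$w_{j\ell,t} = \sum_{k=0}^{10} C_\ell(k)\, B_j(x_{t-k}),$$

where $B$ is a natural cubic spline in the exposure (df 4, knots at the
10th/75th/90th percentiles) and $C$ a natural spline in the lag (knots at
lags 2, 5, 8). The exposure $x$ is the daily mean of the hourly
across-station median temperature (T_med) or NOAA heat index (HI_med).
Duration indicators (1 when the day's count of hours above the hourly-HI
Q90/Q95/Q97.5 exceeds the 90th percentile of that count's distribution)
enter with a linear exposure transform and the same lag spline.

Results are reported as relative risks centered at the exposure mean:
cumulative RR curves with 95 % Wald CIs, lag-specific curves, RRs at the
75th/90th exposure percentiles, the first exposure value whose CI lower
bound exceeds 1 ("risk threshold"), duration-indicator RRs, and AIC/qAIC
model comparison across exposure variants.

## Worked example

Run the pipeline in synthetic mode — multi-station hourly weather with a
known injected exposure–response surface (cumulative RR 1.12 at the
temperature Q90) and Poisson-ish counts around a trend/season/dow
baseline:

```python
from heatmort import heat_index
print(f"HI(30 C, 70%) = {heat_index(30.0, 70.0):.2f} C")

from heatmort.pipeline import RunConfig, run_pipeline
import pandas as pd

cfg = RunConfig(output_dir="out", start_date="2018-01-01",
                end_date="2020-12-31", seed=3)
manifest = run_pipeline(cfg)
print("fitted models:", manifest["n_models"])

rr = pd.read_csv("out/rr_thresholds.csv")
row = rr[(rr.cause == "Natural causes") & (rr.age_group == "65+")
         & (rr.metric == "t_med")].iloc[0]
print(f"first-risk threshold: {row.risk_threshold}")
print(f"RR at Q90: {row.rr_q90:.2f} ({row.rr_q90_low:.2f}-{row.rr_q90_high:.2f})")
```

prints

```
HI(30 C, 70%) = 35.04 C
fitted models: 96
first-risk threshold: 25.5 °C (Q62)
RR at Q90: 1.18 (1.04-1.34)
```

Reading this: 30 °C at 70 % humidity *feels* like 35 °C; 96 models were
fitted (12 eligible cause×age series × 2 exposure metrics × {no
indicator, 3 indicator variants}); for elderly natural-cause mortality
the cumulative relative risk becomes significantly elevated from
25.5 °C (the 62nd percentile of daily mean temperature) upward, and a day
at the 90th temperature percentile carries an estimated 18 % (CI 4–34 %)
excess mortality relative to an average day — consistent with the
injected 12 % truth.

The same run writes `series_summary.csv` (per-series counts, var/mean,
eligibility and likelihood), `indicator_effects.csv` (duration-indicator
RRs), `ic_comparison.csv` (AIC/qAIC per variant) and a `manifest.json`
from which every table regenerates byte-identically.

A CLI wraps the same functions: `heatmort run`, `heatmort simulate`,
`heatmort exposures`, `heatmort series`, `heatmort validate`.

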