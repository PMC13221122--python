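# Methods

## Exposure construction

**Heat index.** The NOAA operational algorithm, evaluated in °F
internally. The simple formula `0.5·[T + 61 + (T − 68)·1.2 + RH·0.094]`
is averaged with T; when that average reaches 80 °F it is replaced by the
Rothfusz regression, minus the low-humidity adjustment
(RH < 13 %, 80–112 °F) and plus the high-humidity adjustment
(RH > 85 %, 80–87 °F). Humidity outside [0, 100] % is an error. Two
regime facts worth knowing: in hot, very dry air (RH ≲ 20 %) the index
legitimately dips several °C *below* the air temperature (evaporative
cooling), and in extreme humid heat the regression extrapolates far above
it; test grids for "HI ≈ T" properties are therefore restricted to
RH ≥ 25 %.

**City series.** The heat index is computed per station-hour *first*,
then the median across available stations is taken per hour; temperature
medians are taken directly over station temperatures. The median (even
count: mean of the two central values) makes the city series robust to
single-station extremes. Station-hours with temperature but missing
humidity contribute to the T median only. Daily T_med/HI_med are the
arithmetic means of the hourly medians; a day needs at least `min_hours`
(default 18/24) city-hours, otherwise it is flagged missing.

**Duration metrics.** Hourly-HI quantiles (Q90/Q95/Q97.5) are computed
over the full input window (configurable) with the type-7
linear-interpolation estimator — fixed so that persisted thresholds are
reproducible. Per day, the number of hours above each quantile is
counted; the "high exposure period" cutoff is the 90th percentile of the
daily count distribution, and a day is flagged high iff its count is
*strictly above* the cutoff (a count equal to the cutoff is normal).

## Cause-of-death series

Deaths are classified by underlying ICD-10 cause into 15 specific groups
plus two aggregates (selected = any specific group; natural = everything
except external causes). Codes are upper-cased and dot-stripped; a
3-character range endpoint covers its 4-character children (I15 covers
I159). R09.2 is carved out of the unspecified R00–R99 group because it is
explicitly assigned to the respiratory group, keeping the specific groups
disjoint.

The external-cause exclusion for "natural" defaults to the published
T00–Y99 rule, with a `conventional` switch for the standard V01–Y98
external-cause chapter. Under the printed rule, U04 (respiratory group)
and U07.1 fall inside the excluded block, so a U04 death counts as
selected-but-not-natural; the conventional switch removes this anomaly.
COVID-19 underlying causes (B34.2, U07.1) are kept out of the selected
aggregate via an explicit exclusion list.

Series are built per cause × age band (0–64 / 65+, an age of 65 falling
in the elderly band), zero-filled over the study window. A series is
eligible for modeling iff its daily median exceeds 1 **and** at most 20 %
of days are zeros; eligible series use a quasipoisson likelihood iff
variance/mean > 1.6 (strictly), Poisson otherwise. Variance uses the
sample (ddof = 1) estimator.

## Spline bases

**Natural cubic splines** use the truncated-power construction with the
natural constraints applied analytically, giving linear tails beyond the
boundary knots. With 3 interior knots and no intercept the basis has 4
columns — the 4-df exposure basis. Exposure boundary knots are the
observed series min/max; interior knots at the empirical
10th/75th/90th percentiles.

**Cyclic cubic splines** are built from cubic B-splines wrapped around
the period (evenly spaced knots), so value, slope and curvature match at
the year seam by construction, and the constant function is exactly
representable. In the baseline design one seasonal column is dropped:
with the intercept present the span is unchanged and the design stays
full rank.

**Cross-basis.** Column (j, ℓ) at day t is
Σ_{k=0..10} C_ℓ(k)·B_j(x_{t−k}). The lag basis is a natural spline over
0–10 with interior knots at lags 2, 5, 8, boundary knots 0 and 10, *and
an intercept column* — the standard DLNM convention, needed so
constant-in-lag effects are representable. This realizes a 5-column lag
basis (so 20 cross-basis columns per smooth exposure); the explicit knot
locations were honored over a literal 3-df reading, and whether the lag
intercept should be dropped is flagged for sensitivity analysis.
Duration indicators use the identity exposure transform with the same lag
spline. The first 10 days (and any day whose lag window touches a
missing exposure) are flagged invalid and dropped from fitting, not
imputed.

## Fitting

A log-link Poisson GLM is fitted by iteratively reweighted least squares
(Fisher scoring; relative deviance change < 1e-9, at most 100 iterations;
non-convergence is flagged on the result, rank deficiency is an error
naming the collinear columns). Quasipoisson keeps the Poisson point
estimates and scales the covariance by the Pearson dispersion
ĉ = X²/(n − p).

The long-term trend is an *unpenalized* natural cubic spline with 6 knots
evenly spaced over the window: with so few knots over a decade-scale
window the smoothing penalty of a penalized equivalent is nearly
inactive, and the unpenalized version keeps the fitter a pure GLM. A
ridge penalty with fixed weight is available behind `fit_glm(ridge=...)`
for sensitivity checks. Holidays are recoded to Sunday in the
day-of-week factor (Sunday is the reference level).

Model comparison uses AIC = −2ℓ + 2p for Poisson and
qAIC = −2ℓ/ĉ + 2(p + 1) for quasipoisson, with ℓ the Poisson
log-likelihood at the quasi fit and the +1 counting the estimated
dispersion (the common Burnham–Anderson convention). Comparing variants
fitted on different observation rows is an error; ties are broken by
variant insertion order.

## Relative-risk inference

All RRs are contrasts against a centering value — the exposure series
mean for smooth exposures, 0 for indicators — so RR(center) = 1 exactly
(and its CI is degenerate there, a zero contrast vector). The cumulative
log-RR at x weights each lag-basis function by its sum over lags 0–10;
lag-specific curves use the single-lag value, and the cumulative log-RR
equals the sum of the 11 lag-specific log-RRs identically. CIs are Wald:
exp(estimate ± 1.96·SE), SE from the quadratic form of the contrast
vector against the coefficient covariance.

The risk threshold is the smallest grid value above the center where the
CI lower bound exceeds 1, scanned on a 0.1 °C grid from the center to the
observed maximum; if the lower bound never crosses, the threshold is
reported as "–". Thresholds are also labelled by their integer empirical
percentile (e.g. "Q79") computed from the full exposure distribution
(including the lag run-in days).

## Synthetic data

The weather generator emulates a Southern-Hemisphere coastal-tropical
multi-station record: annual cycle (peak mid-January, amplitude 3.5 °C
around a 24.2 °C mean), diurnal cycle (peak 14:00, amplitude 3 °C), an
AR(1) synoptic anomaly shared across stations (sd 2 °C, persistence
0.75 — without it the daily mean would be a near-deterministic function
of day-of-year and the exposure would be confounded with the seasonal
spline), station offsets and hourly noise (sd 1 °C), humidity moving
inversely to the diurnal cycle and clipped to [5, 100] %, and
missing-at-random station-hours.

The mortality generator multiplies a baseline (smooth polynomial trend ×
two-harmonic seasonality × day-of-week factors) by
exp(Σ_ℓ log RR(x_{t−ℓ}, ℓ)) for each injected exposure surface, and draws
Poisson counts — or negative-binomial parameterized to
variance = dispersion × mean, since "quasipoisson" is a fitting device,
not a data-generating law. Records are line-listed with ICD codes drawn
uniformly from a configurable pool and ages drawn with a configurable
elderly fraction (default 0.7, uniform within 30–64 / 65–95).

What the generator does **not** emulate: spatial station geography and
urban-heat-island structure, epidemic/pandemic regime shifts, heat-wave
clustering beyond AR(1) persistence, realistic ICD code frequencies, or
informative missingness. Passing recovery tests therefore demonstrate
the estimator's correctness under the assumed model, not robustness to
those real-data features.

## Recovery simulations

The injected truths are chosen to lie in the span of the fitted
cross-basis (log-RR linear in the exposure and constant across lags for
the smooth term; constant across lags for the indicator), so coverage is
evaluated under a correctly specified mean model. The exposure series is
generated once per configuration and held fixed; each replicate redraws
the counts and refits. Default problem sizes: 10 years of daily data
(3650 days, 3 stations), 200 replicates for coverage, 60 per series
length for the RMSE-vs-n curve (1000/3000/9000 days) — sizes at which
the whole suite runs in well under a minute while leaving Monte Carlo
error on a 95 % coverage estimate at about ±1.5 percentage points.

## Numerical choices and edge cases

- Quantiles everywhere: numpy's default type-7 (linear interpolation).
- IRLS initialization: μ₀ = (y + ȳ)/2; linear predictor clipped to ±30
  to guard against overflow in early iterations.
- An infinite upper CI bound (overflowing exp) is reported as `inf`
  rather than an error — it is the honest Wald limit.
- Degenerate inputs: empty station frames give empty city series;
  constant HI collapses all three quantile thresholds to the constant;
  empty death files give all-zero, ineligible series (100 % zeros).
- `compare_models` refuses unequal observation counts rather than
  silently comparing non-nested likelihoods.

## Limitations

- No penalized lag-surface smoothing, no REML/GCV smoothing selection,
  no negative-binomial *fitting* (NB appears only as a generator).
- No air-pollution adjustment, attributable-fraction computation, or
  mortality-displacement (harvesting) analysis.
- Wald CIs throughout; no profile-likelihood or bootstrap intervals.
- The eligibility/likelihood rules are hard thresholds; series near the
  boundaries can flip status under resimulation.
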