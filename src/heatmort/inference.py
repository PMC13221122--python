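"""From fitted models to epidemiological results: centered relative-risk
curves with Wald confidence intervals (cumulative across lags 0..L and
lag-specific), first-significant-risk thresholds, duration-indicator
effects, and AIC/qAIC model-comparison tables.

All RR quantities are contrasts against the centering value (the series
mean for smooth exposures, 0 for indicators): the cumulative log-RR at
exposure x is sum_{j,l} beta_jl * [sum_k C_l(k)] * [B_j(x) - B_j(cen)],
with standard errors from the quadratic form of the contrast vector
against the coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .basis import CrossBasisSpec
from .regression import FitResult

__all__ = [
    "RRPrediction",
    "ThresholdResult",
    "predict_rr",
    "find_first_risk",
    "indicator_effect",
    "compare_models",
    "plot_rr_curve",
]

Z95 = stats.norm.ppf(0.975)  # 1.959964...


@dataclass
class RRPrediction:
    """Centered RR curve: overall cumulative across lags, plus per-lag.

    ``rr[i]`` is the relative risk at ``exposure_grid[i]`` versus the
    centering value; ``by_lag`` has shape (max_lag + 1, n_grid, 3) holding
    (rr, low, high) per lag."""

    exposure_grid: np.ndarray
    rr: np.ndarray
    rr_low: np.ndarray
    rr_high: np.ndarray
    by_lag: np.ndarray
    centering_value: float

    def at(self, x: float) -> tuple[float, float, float]:
        i = int(np.argmin(np.abs(self.exposure_grid - x)))
        return float(self.rr[i]), float(self.rr_low[i]), float(self.rr_high[i])


def _contrasts(spec: CrossBasisSpec, grid: np.ndarray, cen: float) -> np.ndarray:
    """Centered exposure-basis differences B_j(x) - B_j(cen), (n_grid, J)."""
    B = spec.exposure_basis(grid)
    Bc = spec.exposure_basis(np.array([cen]))
    return B - Bc


def predict_rr(fit: FitResult, spec: CrossBasisSpec, grid, cen: float | None = None,
               z: float = Z95) -> RRPrediction:
    """RR curve (with CIs) over an exposure grid, centered at ``cen``.

    Uses the coefficients of the design columns named by the cross-basis
    spec.  Overall cumulative effects weight each lag-basis function by its
    sum over lags 0..max_lag; lag-specific effects use the single-lag value.
    """
    grid = np.asarray(grid, dtype=float)
    if cen is None:
        cen = spec.centering_value
    _, beta, cov = fit.coef(f"{spec.name}:")
    J, Ld = spec.exposure_dim, spec.lag_dim
    if len(beta) != J * Ld:
        raise ValueError("fit does not contain the full cross-basis block")
    if not np.all(np.isfinite(cov)) or np.linalg.matrix_rank(cov) < len(cov):
        raise np.linalg.LinAlgError("singular coefficient covariance")

    dB = _contrasts(spec, grid, cen)                # (n, J)
    C = spec.lag_basis()                            # (L+1, Ld)
    csum = C.sum(axis=0)                            # (Ld,)

    # overall: contrast vector v[n, j*Ld + l] = dB[n, j] * csum[l]
    V = (dB[:, :, None] * csum[None, None, :]).reshape(len(grid), J * Ld)
    est = V @ beta
    se = np.sqrt(np.einsum("ni,ij,nj->n", V, cov, V))
    with np.errstate(over="ignore"):  # an infinite upper bound is legitimate
        rr = np.exp(est)
        lo, hi = np.exp(est - z * se), np.exp(est + z * se)

        by_lag = np.empty((spec.max_lag + 1, len(grid), 3))
        for k in range(spec.max_lag + 1):
            Vk = (dB[:, :, None] * C[k][None, None, :]).reshape(len(grid), J * Ld)
            ek = Vk @ beta
            sk = np.sqrt(np.einsum("ni,ij,nj->n", Vk, cov, Vk))
            by_lag[k, :, 0] = np.exp(ek)
            by_lag[k, :, 1] = np.exp(ek - z * sk)
            by_lag[k, :, 2] = np.exp(ek + z * sk)

    return RRPrediction(exposure_grid=grid, rr=rr, rr_low=lo, rr_high=hi,
                        by_lag=by_lag, centering_value=float(cen))


@dataclass
class ThresholdResult:
    """First exposure value (above the centering point) at which the lower
    CI bound of the cumulative RR exceeds 1, plus RRs at fixed quantiles."""

    exposure_value: float | None
    as_quantile: str | None
    rr_at_q75: tuple[float, float, float] | None = None
    rr_at_q90: tuple[float, float, float] | None = None

    def label(self) -> str:
        if self.exposure_value is None:
            return "-"
        q = f" ({self.as_quantile})" if self.as_quantile else ""
        return f"{self.exposure_value:.1f} °C{q}"


def find_first_risk(pred: RRPrediction, exposure_values: np.ndarray | None = None) -> ThresholdResult:
    """Scan the grid upward from the centering value for the first point
    where rr_low > 1; None (printed as '-') if the lower bound never
    crosses.  When the empirical exposure distribution is supplied the
    threshold is also labelled as its integer percentile (e.g. 'Q79')."""
    grid = pred.exposure_grid
    above = (grid > pred.centering_value) & (pred.rr_low > 1.0)
    if not above.any():
        return ThresholdResult(None, None)
    x = float(grid[np.argmax(above)])
    q = None
    if exposure_values is not None:
        vals = np.asarray(exposure_values, dtype=float)
        vals = vals[np.isfinite(vals)]
        q = f"Q{round(100.0 * np.mean(vals <= x))}"
    return ThresholdResult(x, q)


def indicator_effect(fit: FitResult, spec: CrossBasisSpec, z: float = Z95) -> tuple[float, float, float]:
    """Cumulative RR (with Wald CI) for a duration indicator at 1 versus 0:
    exp of the lag-basis column sums weighted by the fitted coefficients."""
    if spec.exposure != "linear":
        raise ValueError("indicator_effect expects a linear-exposure cross-basis")
    _, beta, cov = fit.coef(f"{spec.name}:")
    csum = spec.lag_basis().sum(axis=0)
    est = float(csum @ beta)
    se = float(np.sqrt(csum @ cov @ csum))
    return float(np.exp(est)), float(np.exp(est - z * se)), float(np.exp(est + z * se))


def plot_rr_curve(pred: RRPrediction, ax=None, title: str | None = None):
    """Overall cumulative RR curve with its CI band (requires matplotlib)."""
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(pred.exposure_grid, pred.rr, color="firebrick")
    ax.fill_between(pred.exposure_grid, pred.rr_low, pred.rr_high,
                    alpha=0.25, color="firebrick", linewidth=0)
    ax.axhline(1.0, color="grey", linewidth=0.8)
    ax.axvline(pred.centering_value, color="grey", linewidth=0.8, linestyle=":")
    ax.set_xlabel("exposure")
    ax.set_ylabel("relative risk (cumulative, lags 0-%d)" % (pred.by_lag.shape[0] - 1))
    if title:
        ax.set_title(title)
    return ax


def compare_models(fits: dict[str, FitResult]) -> pd.DataFrame:
    """AIC/qAIC comparison across model variants fitted to the same rows.

    Raises if the variants were fitted on different numbers of observations
    (information criteria are only comparable on identical data).  Ties are
    broken by the (insertion) order of the variants."""
    n_obs = {v: f.n_obs for v, f in fits.items()}
    if len(set(n_obs.values())) > 1:
        raise ValueError(f"variants fitted on different rows: {n_obs}")
    rows = [{"variant": v, "likelihood": f.likelihood, "ic": f.ic,
             "n_params": f.n_params} for v, f in fits.items()]
    df = pd.DataFrame(rows)
    best = df["ic"].min()
    df["delta_ic"] = df["ic"] - best
    df["best"] = False
    df.loc[df["ic"].idxmin(), "best"] = True
    return df
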