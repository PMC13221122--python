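"""Log-linear count regression by IRLS, with quasipoisson dispersion,
the baseline design (trend + seasonality + day-of-week), and AIC/qAIC.

The mean model is log mu_t = X_t beta where X stacks an intercept, a
natural cubic spline in time (long-term trend, 6 knots over the window),
a cyclic cubic spline in day-of-year (seasonality, 6 knots, period 366),
day-of-week dummies with holidays mapped to Sunday, and the DLNM
cross-basis blocks.  Quasipoisson keeps the Poisson point estimates and
scales the covariance by the Pearson dispersion c-hat = X2 / (n - p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .basis import CyclicSplineSpec, NaturalSplineSpec, cyclic_spline_basis, natural_spline_basis

__all__ = [
    "BaselineSpec",
    "FitResult",
    "dow_factor",
    "build_baseline_design",
    "fit_glm",
    "information_criterion",
]

_WEEKDAYS = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"]


def dow_factor(dates: pd.DatetimeIndex | Sequence, holiday_dates: Iterable = ()) -> pd.Series:
    """Day-of-week level per date, with holidays treated as Sunday."""
    idx = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    holidays = pd.DatetimeIndex(pd.to_datetime(list(holiday_dates))).normalize()
    levels = pd.Series(idx.day_name(), index=idx)
    levels[idx.isin(holidays)] = "Sunday"
    return levels


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline (no-exposure) model structure.

    ``trend_knots`` natural-spline knots are spread evenly over the fitted
    window (boundary knots at the ends); ``season_knots`` is the number of
    cyclic-spline knots over day-of-year.  Sunday is the day-of-week
    reference level, and listed holidays are recoded to Sunday.
    """

    trend_knots: int = 6
    season_knots: int = 6
    season_period: float = 366.0
    holiday_dates: tuple = ()


def build_baseline_design(dates: pd.DatetimeIndex, spec: BaselineSpec = BaselineSpec()) -> pd.DataFrame:
    """Design matrix for the baseline model, one row per date.

    Columns: intercept, trend spline (trend_knots - 1 columns), seasonal
    cyclic spline (season_knots - 1 columns after dropping one for
    identifiability with the intercept), and 6 weekday dummies
    (Sunday = reference).
    """
    idx = pd.DatetimeIndex(pd.to_datetime(dates)).normalize()
    n = len(idx)
    t = (idx - idx[0]).days.to_numpy(dtype=float)

    k = spec.trend_knots
    knots = np.linspace(t.min(), t.max(), k)
    trend_spec = NaturalSplineSpec(interior_knots=tuple(knots[1:-1]),
                                   boundary_knots=(knots[0], knots[-1]),
                                   include_intercept=False)
    trend = natural_spline_basis(t, trend_spec)

    doy = idx.dayofyear.to_numpy(dtype=float)
    season = cyclic_spline_basis(doy, CyclicSplineSpec(spec.season_knots, spec.season_period))
    season = season[:, 1:]  # the dropped column is recoverable from the intercept

    dow = dow_factor(idx, spec.holiday_dates)
    cols = {"intercept": np.ones(n)}
    for j in range(trend.shape[1]):
        cols[f"trend:{j}"] = trend[:, j]
    for j in range(season.shape[1]):
        cols[f"season:{j}"] = season[:, j]
    for day in _WEEKDAYS[:-1]:  # Sunday reference
        cols[f"dow:{day}"] = (dow.to_numpy() == day).astype(float)
    return pd.DataFrame(cols, index=idx)


# ---------------------------------------------------------------------------
# IRLS Poisson / quasipoisson
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted GLM: coefficients, covariance (dispersion-scaled for
    quasipoisson), Pearson dispersion, Poisson log-likelihood and AIC/qAIC."""

    coefficients: np.ndarray
    covariance: np.ndarray
    dispersion: float
    log_likelihood: float
    deviance: float
    ic: float
    n_obs: int
    n_params: int
    likelihood: str
    converged: bool
    names: list[str]
    fitted: np.ndarray

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def coef(self, prefix: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(indices, coefficients, covariance block) for columns whose name
        starts with ``prefix``."""
        idx = np.array([i for i, nm in enumerate(self.names) if nm.startswith(prefix)])
        if len(idx) == 0:
            raise KeyError(f"no design columns match prefix {prefix!r}")
        return idx, self.coefficients[idx], self.covariance[np.ix_(idx, idx)]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coefficients, "se": self.se}, index=self.names)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_glm(y: Sequence[float] | np.ndarray, X: pd.DataFrame | np.ndarray,
            likelihood: str = "poisson", max_iter: int = 100, tol: float = 1e-9,
            ridge: float = 0.0, names: list[str] | None = None) -> FitResult:
    """Fit a log-link Poisson mean model by iteratively reweighted least
    squares; quasipoisson reuses the point estimates and scales the
    covariance by the Pearson dispersion.

    ``ridge`` adds an optional L2 penalty (excluding the intercept) for
    sensitivity analyses with penalized trend splines; default 0 (pure GLM).
    Raises on rank-deficient designs, naming the collinear columns.
    """
    if likelihood not in ("poisson", "quasipoisson"):
        raise ValueError(f"unknown likelihood {likelihood!r}")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = names or [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(~np.isfinite(y)):
        raise ValueError("counts must be finite and non-negative")
    if np.any(~np.isfinite(Xm)):
        raise ValueError("design matrix contains non-finite values")
    n, p = Xm.shape

    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        # pinpoint offending columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(Xm)
        bad = [names[j] for j in range(p) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {p}); "
            f"suspect columns: {bad or 'unidentified'}")

    pen = np.zeros(p) if ridge == 0 else np.full(p, ridge)
    if ridge and "intercept" in names:
        pen[names.index("intercept")] = 0.0

    mu = np.clip((y + np.mean(y)) / 2.0, 1e-8, None)
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    converged = False
    for _ in range(max_iter):
        w = mu  # canonical log link: W = mu
        z = eta + (y - mu) / mu
        WX = Xm * w[:, None]
        H = Xm.T @ WX + np.diag(pen)
        beta = np.linalg.solve(H, WX.T @ z)
        eta = np.clip(Xm @ beta, -30, 30)
        mu = np.exp(eta)
        new_dev = _poisson_deviance(y, mu)
        if abs(new_dev - dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev

    H = Xm.T @ (Xm * mu[:, None]) + np.diag(pen)
    cov_unit = np.linalg.inv(H)
    pearson = float(np.sum((y - mu) ** 2 / mu))
    chat = pearson / (n - p) if n > p else np.nan
    if likelihood == "quasipoisson":
        dispersion = chat
        cov = cov_unit * dispersion
    else:
        dispersion = 1.0
        cov = cov_unit
    ll = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))

    fit = FitResult(coefficients=beta, covariance=cov, dispersion=dispersion,
                    log_likelihood=ll, deviance=dev, ic=np.nan, n_obs=n, n_params=p,
                    likelihood=likelihood, converged=converged, names=names, fitted=mu)
    fit.ic = information_criterion(fit)
    return fit


def information_criterion(fit: FitResult) -> float:
    """AIC for Poisson fits; qAIC = -2 l / c-hat + 2 (p + 1) for
    quasipoisson, where l is the Poisson log-likelihood at the quasi fit
    and the +1 counts the estimated dispersion."""
    if fit.likelihood == "poisson":
        return -2.0 * fit.log_likelihood + 2.0 * fit.n_params
    return -2.0 * fit.log_likelihood / fit.dispersion + 2.0 * (fit.n_params + 1)
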