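"""Spline bases and the exposure x lag cross-basis.

Three constructions used throughout the model:

* natural cubic splines with explicit interior/boundary knots (exposure
  dimension and long-term trend),
* cyclic cubic splines over day-of-year (seasonality), built from
  period-wrapped cubic B-splines so value, slope and curvature match at
  the year seam,
* the cross-basis of a distributed lag nonlinear model (DLNM): the tensor
  of an exposure basis with a lag basis over lags 0..L, whose column
  (j, l) at day t is sum_k C_l(k) * B_j(x_{t-k}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "NaturalSplineSpec",
    "CyclicSplineSpec",
    "CrossBasisSpec",
    "CrossBasisMatrix",
    "natural_spline_basis",
    "cyclic_spline_basis",
    "build_crossbasis",
    "build_linear_lagged",
]


# ---------------------------------------------------------------------------
# natural cubic splines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NaturalSplineSpec:
    """Natural cubic spline: cubic between knots, linear beyond the boundary.

    Basis dimension is ``len(interior_knots) + 1`` plus one if
    ``include_intercept``.  Three interior knots without intercept give the
    4-df exposure basis used for daily mean temperature / heat index.
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    include_intercept: bool = False

    def __post_init__(self) -> None:
        ik = tuple(float(k) for k in self.interior_knots)
        lo, hi = (float(b) for b in self.boundary_knots)
        if not lo < hi:
            raise ValueError(f"boundary knots must be increasing, got ({lo}, {hi})")
        if any(not lo < k < hi for k in ik):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if list(ik) != sorted(ik):
            raise ValueError("interior knots must be sorted")
        object.__setattr__(self, "interior_knots", ik)
        object.__setattr__(self, "boundary_knots", (lo, hi))

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray(
            [self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]]
        )

    @property
    def dim(self) -> int:
        return len(self.interior_knots) + 1 + int(self.include_intercept)


def natural_spline_basis(x: Sequence[float] | np.ndarray, spec: NaturalSplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Uses the truncated-power construction with the natural (linear tail)
    constraints applied analytically: with knots xi_1 < ... < xi_K the basis
    is {1, x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}} where
    ``d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k)``.
    The leading constant column is dropped unless the spec asks for it.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("natural_spline_basis requires finite x")
    knots = spec.all_knots
    K = len(knots)

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - knots[K - 1], 0.0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [np.ones_like(x), x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    out = np.column_stack(cols)
    if not spec.include_intercept:
        out = out[:, 1:]
    return out


# ---------------------------------------------------------------------------
# cyclic cubic splines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CyclicSplineSpec:
    """Cyclic cubic spline with ``n_knots`` evenly spaced knots per period.

    Built from cubic B-splines wrapped around the period, so the basis is
    C2-periodic by construction.  Dimension equals ``n_knots``; the constant
    function lies in the span (B-splines sum to one).
    """

    n_knots: int
    period: float = 366.0

    def __post_init__(self) -> None:
        if self.n_knots < 3:
            raise ValueError("cyclic spline needs at least 3 knots")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def dim(self) -> int:
        return self.n_knots


def cyclic_spline_basis(doy: Sequence[float] | np.ndarray, spec: CyclicSplineSpec) -> np.ndarray:
    """Periodic cubic basis evaluated at day-of-year values (1-based).

    ``doy`` is reduced modulo the period, so evaluating at doy = period + 1
    reproduces the row for doy = 1 exactly.
    """
    doy = np.asarray(doy, dtype=float)
    k, period = spec.n_knots, spec.period
    x = np.mod(doy - 1.0, period)
    h = period / k
    # uniform knot vector extended by 3 on each side for degree-3 B-splines
    t = np.arange(-3, k + 4) * h
    dm = BSpline.design_matrix(x, t, 3).toarray()  # columns i = -3 .. k-1 (k+3 of them)
    out = np.zeros((len(x), k))
    for i in range(dm.shape[1]):
        out[:, (i - 3) % k] += dm[:, i]
    return out


# ---------------------------------------------------------------------------
# cross-basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossBasisSpec:
    """Definition of the exposure x lag tensor basis.

    ``exposure`` is either a natural-spline spec (smooth exposures) or the
    string ``"linear"`` (identity transform, used for 0/1 duration
    indicators).  The lag basis is a natural spline over 0..max_lag and by
    convention includes an intercept column so constant-in-lag effects are
    representable.
    """

    exposure: NaturalSplineSpec | Literal["linear"]
    lag: NaturalSplineSpec
    max_lag: int = 10
    centering_value: float = 0.0
    name: str = "cb"

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")

    @property
    def exposure_dim(self) -> int:
        return 1 if self.exposure == "linear" else self.exposure.dim

    @property
    def lag_dim(self) -> int:
        return self.lag.dim

    @property
    def n_columns(self) -> int:
        return self.exposure_dim * self.lag_dim

    def exposure_basis(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.exposure == "linear":
            return x.reshape(-1, 1)
        return natural_spline_basis(x, self.exposure)

    def lag_basis(self) -> np.ndarray:
        """Lag-basis matrix C with one row per lag 0..max_lag."""
        return natural_spline_basis(np.arange(self.max_lag + 1, dtype=float), self.lag)

    def column_names(self) -> list[str]:
        return [
            f"{self.name}:e{j}:l{l}"
            for j in range(self.exposure_dim)
            for l in range(self.lag_dim)
        ]


def default_lag_spec(max_lag: int = 10, knots: Sequence[float] = (2.0, 5.0, 8.0)) -> NaturalSplineSpec:
    """Natural spline over the lag axis with boundary knots at 0 and max_lag,
    interior knots front-loaded toward later lags, intercept included."""
    return NaturalSplineSpec(
        interior_knots=tuple(knots),
        boundary_knots=(0.0, float(max_lag)),
        include_intercept=True,
    )


@dataclass
class CrossBasisMatrix:
    """Realized cross-basis design block.

    ``values`` has one row per input day and ``spec.n_columns`` columns;
    rows with incomplete lag history (the first ``max_lag`` days, or days
    whose lag window contains a missing exposure) are flagged invalid and
    left NaN.
    """

    values: np.ndarray
    names: list[str]
    valid: np.ndarray  # boolean, per row
    spec: CrossBasisSpec
    index: np.ndarray | None = field(default=None)  # optional date labels


def build_crossbasis(x: Sequence[float] | np.ndarray, spec: CrossBasisSpec,
                     index: np.ndarray | None = None) -> CrossBasisMatrix:
    """Build the DLNM cross-basis for a daily exposure series.

    Column (j, l) at day t is ``sum_{k=0..max_lag} C_l(k) * B_j(x_{t-k})``
    with B the exposure basis and C the lag basis.  Missing exposure values
    (NaN) invalidate every row whose lag window touches them.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    L = spec.max_lag
    if n < L + 1:
        raise ValueError(f"series of length {n} shorter than max_lag + 1 = {L + 1}")

    miss = ~np.isfinite(x)
    B = spec.exposure_basis(np.where(miss, 0.0, x))  # placeholder at missing
    B[miss] = np.nan
    C = spec.lag_basis()  # (L+1) x lag_dim

    J, Ld = spec.exposure_dim, spec.lag_dim
    out = np.zeros((n, J * Ld))
    for k in range(L + 1):
        Bk = B[: n - k] if k else B
        # day t receives B[t-k, j] * C[k, l]
        contrib = Bk[:, :, None] * C[k][None, None, :]
        out[k:, :] += contrib.reshape(n - k, J * Ld)

    valid = np.ones(n, dtype=bool)
    valid[:L] = False
    if miss.any():
        # a missing day contaminates itself and the next L days
        bad = np.convolve(miss.astype(int), np.ones(L + 1, dtype=int))[:n] > 0
        valid &= ~bad
    out[~valid] = np.nan
    return CrossBasisMatrix(values=out, names=spec.column_names(), valid=valid,
                            spec=spec, index=None if index is None else np.asarray(index))


def build_linear_lagged(indicator: Sequence[float] | np.ndarray, lag_spec: NaturalSplineSpec,
                        max_lag: int = 10, name: str = "ind",
                        index: np.ndarray | None = None) -> CrossBasisMatrix:
    """Cross-basis for a 0/1 duration indicator: identity exposure transform,
    spline lag structure.  Centering value is 0 (the 'normal' level)."""
    arr = np.asarray(indicator, dtype=float)
    finite = arr[np.isfinite(arr)]
    if not np.all(np.isin(finite, (0.0, 1.0))):
        raise ValueError("indicator series must contain only 0/1 values")
    spec = CrossBasisSpec(exposure="linear", lag=lag_spec, max_lag=max_lag,
                          centering_value=0.0, name=name)
    return build_crossbasis(arr, spec, index=index)
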