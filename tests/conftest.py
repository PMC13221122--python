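import numpy as np
import pandas as pd
import pytest

from heatmort.basis import CrossBasisSpec, NaturalSplineSpec, default_lag_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def exposure_spec():
    """A 4-df natural-spline exposure basis over a temperature-like range."""
    return NaturalSplineSpec(interior_knots=(21.0, 27.0, 29.0),
                             boundary_knots=(15.0, 35.0),
                             include_intercept=False)


@pytest.fixture
def crossbasis_spec(exposure_spec):
    return CrossBasisSpec(exposure=exposure_spec, lag=default_lag_spec(),
                          max_lag=10, centering_value=24.0, name="cb")


@pytest.fixture
def small_station_frame():
    """Three stations, two full days of hourly records, no missingness."""
    hours = pd.date_range("2023-01-01", "2023-01-02 23:00", freq="h")
    frames = []
    for sid, offset in (("A", 0.0), ("B", 1.0), ("C", -1.0)):
        frames.append(pd.DataFrame({
            "datetime": hours,
            "station_id": sid,
            "temp_c": 24.0 + offset + 2.0 * np.cos(2 * np.pi * (hours.hour - 14) / 24),
            "rh_pct": 70.0,
        }))
    return pd.concat(frames, ignore_index=True)


def brute_force_crossbasis(x, spec):
    """Explicit double-sum oracle for the cross-basis: column (j, l) at day t
    is sum_k C_l(k) * B_j(x_{t-k}), computed with plain Python loops."""
    x = np.asarray(x, dtype=float)
    B = spec.exposure_basis(x)
    C = spec.lag_basis()
    n, J, Ld, L = len(x), B.shape[1], C.shape[1], spec.max_lag
    out = np.full((n, J * Ld), np.nan)
    for t in range(L, n):
        for j in range(J):
            for l in range(Ld):
                out[t, j * Ld + l] = sum(C[k, l] * B[t - k, j] for k in range(L + 1))
    return out
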