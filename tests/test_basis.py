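import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from heatmort.basis import (
    CrossBasisSpec,
    CyclicSplineSpec,
    NaturalSplineSpec,
    build_crossbasis,
    build_linear_lagged,
    cyclic_spline_basis,
    default_lag_spec,
    natural_spline_basis,
)
from conftest import brute_force_crossbasis


def _span_residual(A, B):
    """Largest residual of projecting columns of A onto the column space of B."""
    coefs, *_ = np.linalg.lstsq(B, A, rcond=None)
    return np.max(np.abs(A - B @ coefs))


class TestNaturalSpline:
    def test_dimension_matches_df4_configuration(self, exposure_spec):
        x = np.linspace(16, 34, 40)
        assert natural_spline_basis(x, exposure_spec).shape == (40, 4)
        with_icept = NaturalSplineSpec(exposure_spec.interior_knots,
                                       exposure_spec.boundary_knots, include_intercept=True)
        assert natural_spline_basis(x, with_icept).shape == (40, 5)

    def test_linear_beyond_boundary(self, exposure_spec):
        # evaluate far beyond the upper boundary: second differences vanish
        x = np.array([36.0, 40.0, 44.0, 48.0])
        B = natural_spline_basis(x, exposure_spec)
        second_diff = B[2:] - 2 * B[1:-1] + B[:-2]
        assert np.max(np.abs(second_diff)) < 1e-8
        x = np.array([14.0, 10.0, 6.0, 2.0])
        B = natural_spline_basis(x, exposure_spec)
        second_diff = B[2:] - 2 * B[1:-1] + B[:-2]
        assert np.max(np.abs(second_diff)) < 1e-8

    def test_span_matches_cardinal_interpolation_oracle(self, exposure_spec, rng):
        # independent oracle: natural cubic splines interpolating unit
        # vectors at the knots span the full K-dimensional spline space
        knots = exposure_spec.all_knots
        x = rng.uniform(knots[0], knots[-1], 100)
        impl = natural_spline_basis(
            x, NaturalSplineSpec(exposure_spec.interior_knots,
                                 exposure_spec.boundary_knots, include_intercept=True))
        oracle = np.column_stack([
            CubicSpline(knots, np.eye(len(knots))[i], bc_type="natural")(x)
            for i in range(len(knots))])
        assert _span_residual(impl, oracle) < 1e-8
        assert _span_residual(oracle, impl) < 1e-8

    def test_invalid_inputs(self, exposure_spec):
        with pytest.raises(ValueError):
            natural_spline_basis(np.array([1.0, np.nan]), exposure_spec)
        with pytest.raises(ValueError):
            NaturalSplineSpec((10.0,), (15.0, 35.0))  # knot outside boundary
        with pytest.raises(ValueError):
            NaturalSplineSpec((20.0,), (35.0, 15.0))  # reversed boundary


class TestCyclicSpline:
    def test_periodicity_at_seam(self):
        spec = CyclicSplineSpec(n_knots=6, period=366.0)
        assert np.allclose(cyclic_spline_basis([1.0], spec),
                           cyclic_spline_basis([367.0], spec))
        # C2 continuity: basis is smooth across the seam
        eps = 1e-5
        left = cyclic_spline_basis([366.0 + 1.0 - eps], spec)
        right = cyclic_spline_basis([1.0 + eps], spec)
        assert np.allclose(left, right, atol=1e-3)

    def test_constant_in_span(self):
        spec = CyclicSplineSpec(n_knots=6, period=366.0)
        B = cyclic_spline_basis(np.arange(1.0, 367.0), spec)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_recovers_sinusoid(self):
        spec = CyclicSplineSpec(n_knots=6, period=366.0)
        doy = np.arange(1.0, 367.0)
        target = np.sin(2 * np.pi * doy / 366.0)
        B = cyclic_spline_basis(doy, spec)
        coefs, *_ = np.linalg.lstsq(B, target, rcond=None)
        assert np.max(np.abs(B @ coefs - target)) < 0.05  # < 5 % of amplitude

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError):
            CyclicSplineSpec(n_knots=2)


class TestCrossBasis:
    def test_matches_double_sum_oracle(self, crossbasis_spec, rng):
        x = rng.uniform(16, 34, 30)
        cbm = build_crossbasis(x, crossbasis_spec)
        oracle = brute_force_crossbasis(x, crossbasis_spec)
        valid = cbm.valid
        assert np.nanmax(np.abs(cbm.values[valid] - oracle[valid])) < 1e-10
        assert not valid[:10].any() and valid[10:].all()

    def test_linear_exposure_constant_lag_is_moving_sum(self, rng):
        # identity exposure with a constant lag function reduces to the
        # 11-day moving sum of the series
        lag = NaturalSplineSpec((), (0.0, 10.0), include_intercept=True)
        # intercept-only lag basis: dimension 1+1=2 includes the linear term;
        # select the constant component via a 1-column variant
        x = rng.integers(0, 2, 60).astype(float)
        cbm = build_linear_lagged(x, lag, max_lag=10)
        C = cbm.spec.lag_basis()
        moving = np.convolve(x, np.ones(11))[:60]
        # reconstruct the constant lag function from the basis
        w, *_ = np.linalg.lstsq(C, np.ones(11), rcond=None)
        combo = cbm.values[cbm.valid] @ w
        assert np.allclose(combo, moving[cbm.valid], atol=1e-10)

    def test_additivity_for_linear_exposure(self, rng):
        lag = default_lag_spec()
        a = rng.integers(0, 2, 50).astype(float)
        b = rng.integers(0, 2, 50).astype(float)
        spec = CrossBasisSpec(exposure="linear", lag=lag, max_lag=10, name="v")
        both = build_crossbasis(a + b, spec).values
        sep = build_crossbasis(a, spec).values + build_crossbasis(b, spec).values
        valid = ~np.isnan(both[:, 0])
        assert np.allclose(both[valid], sep[valid])

    def test_shift_equivariance(self, crossbasis_spec, rng):
        x = rng.uniform(16, 34, 40)
        shifted = np.concatenate([[20.0], x[:-1]])
        a = build_crossbasis(x, crossbasis_spec).values
        b = build_crossbasis(shifted, crossbasis_spec).values
        assert np.allclose(b[12:], a[11:-1])

    def test_max_lag_zero_reduces_to_exposure_basis(self, exposure_spec, rng):
        lag = NaturalSplineSpec((), (0.0, 1.0), include_intercept=True)
        # at max_lag=0 the lag basis evaluates at lag 0 only
        spec = CrossBasisSpec(exposure=exposure_spec, lag=lag, max_lag=0, name="v")
        x = rng.uniform(16, 34, 20)
        cbm = build_crossbasis(x, spec)
        B = exposure_spec and spec.exposure_basis(x)
        C0 = spec.lag_basis()[0]
        expected = np.concatenate([B[:, [j]] * C0 for j in range(B.shape[1])], axis=1)
        assert np.allclose(cbm.values, expected)

    def test_short_series_rejected(self, crossbasis_spec):
        with pytest.raises(ValueError, match="shorter"):
            build_crossbasis(np.arange(5.0), crossbasis_spec)

    def test_missing_exposure_invalidates_lag_window(self, crossbasis_spec, rng):
        x = rng.uniform(16, 34, 40)
        x[20] = np.nan
        cbm = build_crossbasis(x, crossbasis_spec)
        assert not cbm.valid[20:31].any()
        assert cbm.valid[31:].all() and cbm.valid[10:20].all()


class TestLinearLagged:
    def test_all_zero_indicator(self):
        cbm = build_linear_lagged(np.zeros(30), default_lag_spec())
        assert np.allclose(cbm.values[cbm.valid], 0.0)

    def test_isolated_one_has_lag_support(self):
        x = np.zeros(40)
        x[20] = 1.0
        cbm = build_linear_lagged(x, default_lag_spec())
        nz = np.abs(cbm.values[cbm.valid]).sum(axis=1) > 1e-12
        days = np.arange(40)[cbm.valid][nz]
        assert days.min() == 20 and days.max() == 30

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            build_linear_lagged(np.array([0.0, 0.5, 1.0] * 10), default_lag_spec())

    def test_matches_double_sum_oracle(self, rng):
        x = rng.integers(0, 2, 30).astype(float)
        cbm = build_linear_lagged(x, default_lag_spec())
        oracle = brute_force_crossbasis(x, cbm.spec)
        valid = cbm.valid
        assert np.nanmax(np.abs(cbm.values[valid] - oracle[valid])) < 1e-10
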