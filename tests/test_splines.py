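"""Spline bases, cross-basis and curve reduction against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hppeval.splines import (
    EmpiricalPercentiles,
    LagBasisSpec,
    ReducedCurve,
    VarBasisSpec,
    bspline_basis,
    cross_basis,
    default_lag_spec,
    find_mmt,
    log_lag_knots,
    natural_lag_basis,
    natural_spline_basis,
    reduce_to_overall,
)

VSPEC = VarBasisSpec(internal_knots=(12.0, 22.0), boundary=(0.0, 30.0))
LSPEC = default_lag_spec(10, 2)


def brute_force_lag_sum(x, full_coef, var_spec, lag_spec, t):
    """Independent double-loop evaluation of sum_l f(x_{t-l}, l)."""
    vdim, ldim = var_spec.dimension, lag_spec.dimension
    C = np.asarray(full_coef).reshape(vdim, ldim)
    total = 0.0
    for lag in range(lag_spec.max_lag + 1):
        Bv = bspline_basis(np.array([x[t - lag]]), var_spec)[0]
        Bl = natural_lag_basis(np.array([lag]), lag_spec)[0]
        for j in range(vdim):
            for k in range(ldim):
                total += C[j, k] * Bv[j] * Bl[k]
    return total


class TestBSpline:
    def test_partition_of_unity_with_intercept(self, rng):
        x = rng.uniform(0, 30, 200)
        B = bspline_basis(x, VSPEC, intercept=True)
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_is_degree_plus_knots(self):
        B = bspline_basis(np.linspace(0, 30, 11), VSPEC)
        assert B.shape[1] == 4

    def test_repeated_value_gives_identical_rows(self):
        B = bspline_basis(np.full(7, 17.3), VSPEC)
        assert np.allclose(B, B[0])

    def test_out_of_boundary_clamped(self):
        B = bspline_basis(np.array([-100.0, 0.0, 30.0, 1e3]), VSPEC)
        assert np.allclose(B[0], B[1]) and np.allclose(B[2], B[3])

    def test_nonincreasing_knots_rejected(self):
        with pytest.raises(ValueError):
            VarBasisSpec(internal_knots=(22.0, 12.0), boundary=(0.0, 30.0))


class TestNaturalSpline:
    def test_second_derivative_zero_at_boundary(self):
        # central differences straddling the boundary knot have an O(h)
        # leading error (the third derivative jumps there), so extrapolate
        # the h -> 0 limit from two step sizes
        def cd(x0, h):
            pts = np.array([x0 - h, x0, x0 + h])
            B = natural_spline_basis(pts, np.array(LSPEC.internal_knots), (0.0, 10.0))
            return (B[0] - 2 * B[1] + B[2]) / h**2

        for x0 in (0.0, 10.0):
            limit = 2 * cd(x0, 1e-3) - cd(x0, 2e-3)
            assert np.all(np.abs(limit) < 1e-6)

    def test_linear_beyond_boundary(self):
        x = np.array([12.0, 13.0, 14.0, 15.0])
        B = natural_spline_basis(x, np.array(LSPEC.internal_knots), (0.0, 10.0))
        second_diffs = B[2:] - 2 * B[1:-1] + B[:-2]
        assert np.allclose(second_diffs, 0.0, atol=1e-9)

    def test_dimension_and_rank(self, rng):
        x = rng.uniform(0, 10, 40)
        B = natural_lag_basis(x, LSPEC)
        assert B.shape[1] == 4
        assert np.linalg.matrix_rank(B) == 4


class TestLogLagKnots:
    def test_two_knots_match_closed_form(self):
        knots = log_lag_knots(10, 2)
        assert np.allclose(knots, [10 ** (1 / 3), 10 ** (2 / 3)], atol=1e-12)

    def test_single_knot_at_geometric_midpoint(self):
        assert np.isclose(log_lag_knots(10, 1)[0], np.sqrt(10.0))

    def test_knots_strictly_inside_window(self):
        for n in (1, 2, 3):
            k = log_lag_knots(10, n)
            assert np.all(k > 0) and np.all(k < 10)

    def test_too_many_knots_rejected(self):
        with pytest.raises(ValueError):
            log_lag_knots(10, 10)


class TestCrossBasis:
    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 30, 30)
            cb, complete = cross_basis(x, VSPEC, LSPEC)
            coef = rng.normal(size=16)
            for t in np.flatnonzero(complete)[:5]:
                assert np.isclose(
                    cb[t] @ coef,
                    brute_force_lag_sum(x, coef, VSPEC, LSPEC, t),
                    atol=1e-10,
                )

    def test_constant_series_rows_identical(self):
        cb, complete = cross_basis(np.full(30, 15.0), VSPEC, LSPEC)
        rows = cb[complete]
        assert np.allclose(rows, rows[0])

    def test_sixteen_columns_and_incomplete_rows_flagged(self, rng):
        cb, complete = cross_basis(rng.uniform(0, 30, 50), VSPEC, LSPEC)
        assert cb.shape[1] == 16
        assert not complete[:10].any() and complete[10:].all()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            cross_basis(np.zeros(10), VSPEC, LSPEC)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_linearity_in_coefficients(self, seed):
        r = np.random.default_rng(seed)
        x = r.uniform(0, 30, 25)
        cb, _ = cross_basis(x, VSPEC, LSPEC)
        c1, c2 = r.normal(size=16), r.normal(size=16)
        a, b = r.normal(), r.normal()
        assert np.allclose(cb @ (a * c1 + b * c2), a * (cb @ c1) + b * (cb @ c2), atol=1e-9)


class TestReduction:
    def test_overall_log_rr_equals_lag_sum(self, rng):
        x = rng.uniform(0, 30, 60)
        coef = rng.normal(size=16) * 0.1
        vcov = np.eye(16) * 1e-4
        center = 15.0
        curve = reduce_to_overall(coef, vcov, VSPEC, LSPEC, center)
        xx = np.full(LSPEC.max_lag + 1, 0.0)
        for xq in rng.uniform(0, 30, 50):
            # brute force: hold exposure constant at xq over all lags
            ref = brute_force_lag_sum(np.full(11, xq), coef, VSPEC, LSPEC, 10)
            base = brute_force_lag_sum(np.full(11, center), coef, VSPEC, LSPEC, 10)
            assert np.isclose(curve.log_rr(np.array([xq]))[0], ref - base, atol=1e-10)

    def test_zero_coefficients_give_flat_curve(self):
        curve = reduce_to_overall(np.zeros(16), np.zeros((16, 16)), VSPEC, LSPEC, 10.0)
        assert np.allclose(curve.coef, 0.0)
        assert np.allclose(curve.log_rr(np.linspace(0, 30, 20)), 0.0)

    def test_recentering_zeroes_log_rr_at_center(self, rng):
        coef = rng.normal(size=16)
        curve = reduce_to_overall(coef, np.eye(16) * 1e-4, VSPEC, LSPEC, 5.0)
        re = curve.recentered(21.7)
        assert re.log_rr(np.array([21.7]))[0] == 0.0

    def test_recentering_commutes_with_reduction(self, rng):
        coef = rng.normal(size=16)
        c1 = reduce_to_overall(coef, np.eye(16) * 1e-4, VSPEC, LSPEC, 5.0).recentered(20.0)
        c2 = reduce_to_overall(coef, np.eye(16) * 1e-4, VSPEC, LSPEC, 20.0)
        x = np.linspace(0, 30, 31)
        assert np.allclose(c1.log_rr(x), c2.log_rr(x), atol=1e-12)

    def test_roundtrip_serialization(self, rng):
        coef = rng.normal(size=16)
        curve = reduce_to_overall(coef, np.eye(16) * 1e-4, VSPEC, LSPEC, 12.0,
                                  percentiles={50.0: 15.0, 90.0: 24.0})
        back = ReducedCurve.from_dict(curve.to_dict())
        assert np.allclose(back.coef, curve.coef)
        assert np.allclose(back.vcov, curve.vcov)
        assert back.percentiles == curve.percentiles


class TestFindMMT:
    def _curve_from_function(self, f):
        """Project f onto the reduced basis by least squares (exact for
        piecewise quadratics)."""
        grid = np.linspace(0, 30, 400)
        B = bspline_basis(grid, VSPEC)
        coef, *_ = np.linalg.lstsq(B, f(grid) - f(0.0), rcond=None)
        return ReducedCurve(coef=coef, vcov=np.eye(4) * 1e-6, var_spec=VSPEC, center=0.0)

    def test_quadratic_minimum_recovered(self):
        xstar = 17.4
        curve = self._curve_from_function(lambda x: 0.01 * (x - xstar) ** 2)
        mmt, _ = find_mmt(curve, (1.0, 29.0), grid_step=0.05)
        assert abs(mmt - xstar) <= 0.05 + 1e-9

    def test_monotone_curve_hits_lower_bound(self):
        curve = self._curve_from_function(lambda x: 0.05 * x)
        mmt, _ = find_mmt(curve, (2.0, 28.0), grid_step=0.1)
        assert mmt == 2.0

    def test_flat_curve_ties_break_low(self):
        curve = ReducedCurve(coef=np.zeros(4), vcov=np.zeros((4, 4)), var_spec=VSPEC, center=0.0)
        mmt, _ = find_mmt(curve, (3.0, 27.0), grid_step=0.1)
        assert mmt == 3.0

    def test_empty_range_rejected(self):
        curve = ReducedCurve(coef=np.zeros(4), vcov=np.zeros((4, 4)), var_spec=VSPEC, center=0.0)
        with pytest.raises(ValueError):
            find_mmt(curve, (5.0, 5.0))


class TestEmpiricalPercentiles:
    def test_roundtrip_on_order_statistics(self, rng):
        vals = rng.normal(20, 5, 500)
        ep = EmpiricalPercentiles(vals)
        p = np.array([5.0, 50.0, 95.0])
        assert np.allclose(ep.to_percentile(ep.to_celsius(p)), p, atol=1e-9)

    def test_monotone(self, rng):
        ep = EmpiricalPercentiles(rng.normal(20, 5, 300))
        x = np.linspace(0, 40, 100)
        assert np.all(np.diff(ep.to_percentile(x)) >= 0)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalPercentiles(np.full(10, 3.0))
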