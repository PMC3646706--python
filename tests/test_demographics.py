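"""Piecewise-linear functions, analytic hazard integrals and inverse sampling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from mscmig.demographics import (
    INFINITY,
    GenerationScale,
    InvalidScaleError,
    PiecewiseLinearFunction,
    RateIntegral,
    SingularPopulationError,
    coalescent_hazard,
    evaluate,
    integrate_hazard,
    migration_hazard,
    pop_size_in_individuals,
    rational_decompose,
    solve_waiting_time,
)

PLF = PiecewiseLinearFunction


@pytest.mark.parametrize(
    "bp,vals,t,expected",
    [
        ([0, 1], [2, 4], 0.5, 3.0),       # midpoint of a linear segment
        ([0, 1], [0.1, 0.1], 0.7, 0.1),   # constant case
        ([0, 1, 2], [1, 3, 3], 1.5, 3.0),  # flat second segment
        ([0, 1], [2, 4], 5.0, 4.0),       # constant extension past the end
        ([0, 1], [2, 4], 1.0, 4.0),       # evaluation at a breakpoint
    ],
)
def test_piecewise_linear_evaluation(bp, vals, t, expected):
    assert evaluate(PLF(bp, vals), t) == pytest.approx(expected)


@given(
    st.lists(st.floats(0, 100), min_size=2, max_size=6, unique=True),
    st.data(),
)
def test_midpoint_is_mean_of_endpoints(times, data):
    """Linear interpolation: the midpoint value is the mean of the endpoints."""
    bp = sorted(times)
    vals = [data.draw(st.floats(0, 50)) for _ in bp]
    f = PLF(bp, vals)
    for (t0, v0), (t1, v1) in zip(zip(bp, vals), zip(bp[1:], vals[1:])):
        assert f((t0 + t1) / 2) == pytest.approx((v0 + v1) / 2, abs=1e-9)


def test_piecewise_linear_validation():
    with pytest.raises(ValueError):
        PLF([1, 0], [1, 1])  # not increasing
    with pytest.raises(ValueError):
        PLF([0, 1], [1, -1])  # negative value
    with pytest.raises(ValueError):
        PLF([0, 1], [1])  # shape mismatch


def test_zero_outside_support():
    m = PLF([1, 2], [0.0, 0.5], zero_outside=True)
    assert m(0.5) == 0.0
    assert m(2.5) == 0.0
    assert m(2.0) == 0.5
    assert m(1.5) == pytest.approx(0.25)


@pytest.mark.parametrize(
    "nu,tau,expected",
    [(0.1, 1e-6, 1e5), (0.1, 1e-3, 100.0), (0.37, 1.0, 0.37)],
)
def test_population_size_scaling(nu, tau, expected):
    """nu = N_e * tau: converting scaled sizes to individual counts."""
    assert pop_size_in_individuals(nu, GenerationScale(tau)) == pytest.approx(expected)


def test_invalid_generation_scale():
    with pytest.raises(InvalidScaleError):
        GenerationScale(0.0)
    with pytest.raises(InvalidScaleError):
        GenerationScale(-1.0)


class TestRationalDecompose:
    def test_all_constant(self):
        assert rational_decompose(1, 0, 1, 0, 1, 0) == (1.0, 0.0, 0.0)

    def test_cancellation(self):
        # t * t / t = t
        assert rational_decompose(0, 1, 0, 1, 0, 1) == (0.0, 1.0, 0.0)

    def test_degenerate_denominator(self):
        with pytest.raises(ZeroDivisionError):
            rational_decompose(1, 1, 1, 1, 0, 0)

    def test_pointwise_identity(self, rng):
        """c0 + c1 t + c2/(a3+b3 t) reproduces the quotient everywhere."""
        for _ in range(20):
            a1, b1, a2, b2 = rng.uniform(-3, 3, size=4)
            a3, b3 = rng.uniform(0.5, 3), rng.uniform(0.1, 2)
            c0, c1, c2 = rational_decompose(a1, b1, a2, b2, a3, b3)
            ts = rng.uniform(0, 5, size=100)
            direct = (a1 + b1 * ts) * (a2 + b2 * ts) / (a3 + b3 * ts)
            recon = c0 + c1 * ts + c2 / (a3 + b3 * ts)
            assert np.max(np.abs(direct - recon)) < 1e-10

    def test_polynomial_branch(self, rng):
        """With a constant denominator the triple is quadratic coefficients."""
        for _ in range(10):
            a1, b1, a2, b2 = rng.uniform(-2, 2, size=4)
            a3 = rng.uniform(0.5, 3)
            c0, c1, c2 = rational_decompose(a1, b1, a2, b2, a3, 0.0)
            ts = rng.uniform(0, 5, size=50)
            direct = (a1 + b1 * ts) * (a2 + b2 * ts) / a3
            recon = c0 + c1 * ts + c2 * ts ** 2
            assert np.max(np.abs(direct - recon)) < 1e-10


def _random_migration_hazard(rng):
    def plf(lo_v, hi_v, n):
        bp = np.sort(rng.uniform(0, 4, size=n))
        bp[0] = 0.0
        return PLF(bp, rng.uniform(lo_v, hi_v, size=n))

    m = plf(0.0, 1.0, rng.integers(2, 5))
    nu_b = plf(0.3, 3.0, rng.integers(2, 5))
    nu_a = plf(0.3, 3.0, rng.integers(2, 5))
    return migration_hazard(m, nu_b, [nu_a]), (m, nu_b, nu_a)


class TestIntegrateHazard:
    def test_constant_coalescent(self):
        h = coalescent_hazard(PLF.constant(2.0), 2)
        assert integrate_hazard(h, 0, 1) == pytest.approx(0.5)

    def test_many_lineages_scale(self):
        # C(4,2) = 6 pairs
        h = coalescent_hazard(PLF.constant(2.0), 4)
        assert integrate_hazard(h, 0, 1) == pytest.approx(3.0)

    def test_constant_migration(self):
        h = migration_hazard(PLF.constant(0.1), PLF.constant(2.0), [PLF.constant(1.0)])
        assert integrate_hazard(h, 0, 2) == pytest.approx(0.4)

    def test_log_term(self):
        # integral of 1/(1+t) over [0,1] = ln 2
        h = migration_hazard(
            PLF.constant(1.0), PLF.constant(1.0), [PLF([0, 1], [1, 2])]
        )
        assert integrate_hazard(h, 0, 1) == pytest.approx(math.log(2), rel=1e-12)

    def test_matches_numerical_quadrature(self, rng):
        """Analytic segment integration equals adaptive quadrature."""
        for _ in range(8):
            h, (m, nu_b, nu_a) = _random_migration_hazard(rng)
            t0, t1 = sorted(rng.uniform(0, 5, size=2))
            ref, _ = quad(
                lambda t: m(t) * nu_b(t) / nu_a(t), t0, t1,
                limit=400,
                points=sorted(
                    set(np.concatenate([m.breakpoints, nu_b.breakpoints,
                                        nu_a.breakpoints]))
                ) if t1 > t0 else None,
            )
            got = integrate_hazard(h, t0, t1)
            assert got == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_additivity(self, rng):
        h, _ = _random_migration_hazard(rng)
        a, b, c = sorted(rng.uniform(0, 5, size=3))
        assert integrate_hazard(h, a, c) == pytest.approx(
            integrate_hazard(h, a, b) + integrate_hazard(h, b, c), rel=1e-12
        )

    def test_singular_population(self):
        with pytest.raises(SingularPopulationError):
            coalescent_hazard(PLF([0, 1], [1.0, 0.0]), 2, 0, 1.0)


class TestSolveWaitingTime:
    def test_exponential_inverse(self):
        r = 0.7
        h = coalescent_hazard(PLF.constant(1.0 / r), 2)
        for u in (0.1, 0.5, 0.95):
            expect = -math.log1p(-u) / r
            assert solve_waiting_time(h, 0.0, u) == pytest.approx(expect, rel=1e-10)

    def test_u_zero_returns_start(self):
        h = coalescent_hazard(PLF.constant(1.0), 2)
        assert solve_waiting_time(h, 0.3, 0.0) == 0.3

    def test_step_hazard(self):
        # zero on [0,1), rate 1 on [1,2]: cumulative 0.5 is reached at t=1.5
        step = PLF([1, 2], [1.0, 1.0], zero_outside=True)
        h = migration_hazard(step, PLF.constant(1.0), [PLF.constant(1.0)], 0, 2)
        u = -math.expm1(-0.5)
        assert solve_waiting_time(h, 0.0, u, horizon=10) == pytest.approx(1.5, rel=1e-9)

    def test_monotone_in_u(self, rng):
        h, _ = _random_migration_hazard(rng)
        us = np.sort(rng.uniform(0, 0.999, size=50))
        ts = [solve_waiting_time(h, 0.2, u) for u in us]
        assert all(a <= b + 1e-12 for a, b in zip(ts, ts[1:]))

    def test_beyond_horizon_is_infinite(self):
        h = coalescent_hazard(PLF.constant(1.0), 2)
        assert solve_waiting_time(h, 0.0, 0.99, horizon=0.01) == INFINITY

    def test_band_exhausted_is_infinite(self):
        band = PLF([0, 1], [0.1, 0.1], zero_outside=True)
        h = migration_hazard(band, PLF.constant(1.0), [PLF.constant(1.0)], 0, 1)
        # total hazard is 0.1; a larger target never happens
        assert solve_waiting_time(h, 0.0, 0.5) == INFINITY

    def test_invalid_u(self):
        h = coalescent_hazard(PLF.constant(1.0), 2)
        with pytest.raises(ValueError):
            solve_waiting_time(h, 0.0, 1.0)

    def test_impossible_events_are_infinite(self):
        # coalescence needs two lineages: the hazard is identically zero
        h = coalescent_hazard(PLF.constant(1.0), 1)
        assert solve_waiting_time(h, 0.0, 0.999) == INFINITY

    def test_round_trip_identity(self, rng):
        """solve(integrate) is the identity to 1e-9 relative tolerance."""
        for _ in range(10):
            h, _ = _random_migration_hazard(rng)
            t0 = float(rng.uniform(0, 1))
            t = t0 + float(rng.uniform(0.01, 3))
            cum = integrate_hazard(h, t0, t)
            if cum <= 0 or cum > 30:
                continue
            u = -math.expm1(-cum)
            back = solve_waiting_time(h, t0, u)
            assert back == pytest.approx(t, rel=1e-9)

    def test_constant_rate_samples_are_exponential(self, rng):
        """Inverse-transform draws pass a KS test against the exponential law."""
        r = 1.7
        h = coalescent_hazard(PLF.constant(1.0 / r), 2)
        us = rng.random(10_000)
        ts = np.array([solve_waiting_time(h, 0.0, u) for u in us])
        p = stats.kstest(ts, stats.expon(scale=1 / r).cdf).pvalue
        assert p > 0.01
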