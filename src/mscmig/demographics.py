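"""Piecewise-linear rate functions and analytic waiting-time machinery.

Every random time the simulator draws -- a coalescent waiting time or a
migration waiting time -- is the first event of a non-homogeneous Poisson
process.  On suitable sub-intervals the event rate is a rational function

    h(t) = (a1 + b1*t) * (a2 + b2*t) / (a3 + b3*t),

the product of two linear functions (e.g. a migration fraction and the
emigrant population size) divided by a third (the receiving population
size).  The cumulative hazard of such a rate has a closed form (polynomial
plus logarithmic terms), so the inverse-transform equation

    int_{t0}^{t} h(s) ds = -log(1 - U),    U ~ Uniform[0, 1)

can be solved exactly up to a safeguarded one-dimensional root search inside
a single sub-interval.  :class:`RateIntegral` caches the sub-interval
decomposition on which all component functions are simultaneously linear.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "INFINITY",
    "GenerationScale",
    "InvalidScaleError",
    "PiecewiseLinearFunction",
    "RateIntegral",
    "SingularPopulationError",
    "coalescent_hazard",
    "evaluate",
    "integrate_hazard",
    "migration_hazard",
    "pop_size_in_individuals",
    "rational_decompose",
    "solve_waiting_time",
]

INFINITY = math.inf


class SingularPopulationError(ValueError):
    """A population size touches zero on an interval where lineages reside.

    The pairwise coalescent rate is ``1/nu(t)``, which diverges as the
    scaled population size ``nu`` approaches zero, so ``nu`` may vanish only
    on intervals that are guaranteed to hold no gene lineages.
    """


class InvalidScaleError(ValueError):
    """Generation time must be strictly positive."""


class PiecewiseLinearFunction:
    """Nonnegative piecewise-linear function of time.

    The function linearly interpolates between ``(breakpoint, value)``
    pairs and extends as a constant beyond the first and last breakpoints.
    With ``zero_outside=True`` the function instead vanishes strictly
    outside ``[breakpoints[0], breakpoints[-1]]`` (evaluation *at* either
    endpoint still returns the stored value); this variant represents
    migration fractions supported on a finite separation interval.

    Parameters
    ----------
    breakpoints
        Strictly increasing times, in model time units (e.g. Myr).
    values
        Nonnegative function values at the breakpoints.
    zero_outside
        If true, the function is zero outside the breakpoint span.
    """

    __slots__ = ("breakpoints", "values", "zero_outside")

    def __init__(self, breakpoints, values, *, zero_outside: bool = False):
        bp = np.atleast_1d(np.asarray(breakpoints, dtype=float))
        vals = np.atleast_1d(np.asarray(values, dtype=float))
        if bp.ndim != 1 or bp.shape != vals.shape or bp.size == 0:
            raise ValueError("breakpoints and values must be matching 1-d sequences")
        if bp.size > 1 and not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if not (np.all(np.isfinite(bp)) and np.all(np.isfinite(vals))):
            raise ValueError("breakpoints and values must be finite")
        if np.any(vals < 0):
            raise ValueError("values must be nonnegative")
        self.breakpoints = bp
        self.values = vals
        self.zero_outside = bool(zero_outside)

    @classmethod
    def constant(cls, value: float) -> "PiecewiseLinearFunction":
        """A function equal to ``value`` at all times."""
        return cls([0.0], [value])

    def __call__(self, t):
        out = np.interp(t, self.breakpoints, self.values)
        if self.zero_outside:
            ta = np.asarray(t, dtype=float)
            out = np.where(
                (ta < self.breakpoints[0]) | (ta > self.breakpoints[-1]), 0.0, out
            )
        if np.ndim(t) == 0:
            return float(out)
        return np.asarray(out, dtype=float)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        pairs = ", ".join(
            f"({t:g}, {v:g})" for t, v in zip(self.breakpoints, self.values)
        )
        tag = ", zero_outside" if self.zero_outside else ""
        return f"PiecewiseLinearFunction([{pairs}]{tag})"


def evaluate(f: PiecewiseLinearFunction, t):
    """Evaluate ``f`` at time ``t`` (linear interpolation, constant tails)."""
    return f(t)


@dataclass(frozen=True)
class GenerationScale:
    """Generation time ``tau`` expressed in the model's time unit.

    The simulator parametrizes populations by the scaled size
    ``nu = N_e * tau``; the coalescent rate of a pair is ``1/nu``.  The
    generation time matters only when converting ``nu`` back into a head
    count of individuals, or model time into generations.
    """

    tau: float

    def __post_init__(self):
        if not (self.tau > 0 and math.isfinite(self.tau)):
            raise InvalidScaleError(f"generation time must be positive, got {self.tau}")


def pop_size_in_individuals(nu: float, scale: GenerationScale) -> float:
    """Effective number of individuals ``N_e = nu / tau``."""
    if nu < 0:
        raise ValueError("nu must be nonnegative")
    return nu / scale.tau


def rational_decompose(a1, b1, a2, b2, a3, b3):
    """Decompose ``(a1+b1 t)(a2+b2 t)/(a3+b3 t)`` for term-wise integration.

    Returns a triple ``(c0, c1, c2)``.  When ``b3 != 0`` the identity

        (a1+b1 t)(a2+b2 t)/(a3+b3 t) = c0 + c1*t + c2/(a3+b3 t)

    holds on any interval avoiding the pole.  When ``b3 == 0`` the quotient
    is a plain quadratic polynomial and the returned triple holds its
    coefficients, ``c0 + c1*t + c2*t**2``; the caller integrates that branch
    directly rather than forcing a division by ``b3``.
    """
    if a3 == 0 and b3 == 0:
        raise ZeroDivisionError("degenerate denominator: a3 = b3 = 0")
    p0 = a1 * a2
    p1 = a1 * b2 + b1 * a2
    p2 = b1 * b2
    if b3 == 0:
        return p0 / a3, p1 / a3, p2 / a3
    c1 = p2 / b3
    c0 = (p1 - c1 * a3) / b3
    c2 = p0 - c0 * a3
    return c0, c1, c2


def _segment_integral(coeffs, u0: float, u1: float) -> float:
    """Exact integral of the rational segment rate over ``[u0, u1]``."""
    a1, b1, a2, b2, a3, b3 = coeffs
    p0 = a1 * a2
    p1 = a1 * b2 + b1 * a2
    p2 = b1 * b2
    if p0 == 0.0 and p1 == 0.0 and p2 == 0.0:
        return 0.0
    if b3 == 0.0:
        return (
            p0 * (u1 - u0)
            + p1 * (u1 * u1 - u0 * u0) / 2.0
            + p2 * (u1 ** 3 - u0 ** 3) / 3.0
        ) / a3
    c0, c1, c2 = rational_decompose(a1, b1, a2, b2, a3, b3)
    d0 = a3 + b3 * u0
    d1 = a3 + b3 * u1
    return (
        c0 * (u1 - u0)
        + c1 * (u1 * u1 - u0 * u0) / 2.0
        + (c2 / b3) * math.log(d1 / d0)
    )


class RateIntegral:
    """Cumulative hazard of a piecewise-rational event rate.

    ``bounds`` is an ascending array of ``k + 1`` times whose last entry is
    ``+inf``; on ``[bounds[i], bounds[i+1])`` the rate equals
    ``(a1+b1 t)(a2+b2 t)/(a3+b3 t)`` with ``coeffs[i] = (a1,...,b3)``.  The
    final (unbounded) segment is always constant.  The cumulative integral
    is nondecreasing and additive over abutting intervals.
    """

    __slots__ = ("bounds", "coeffs")

    def __init__(self, bounds: Sequence[float], coeffs):
        self.bounds = [float(b) for b in bounds]
        self.coeffs = [tuple(float(x) for x in c) for c in coeffs]
        if len(self.bounds) != len(self.coeffs) + 1:
            raise ValueError("need one more bound than coefficient tuples")
        if self.bounds[-1] != INFINITY:
            raise ValueError("last bound must be +inf")

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def zero(cls, lo: float = 0.0) -> "RateIntegral":
        return cls([lo, INFINITY], [(0.0, 0.0, 0.0, 0.0, 1.0, 0.0)])

    @classmethod
    def from_components(
        cls,
        numerators: Sequence[PiecewiseLinearFunction],
        denominators: Sequence[PiecewiseLinearFunction],
        lo: float = 0.0,
        hi: float = INFINITY,
    ) -> "RateIntegral":
        """Build the hazard ``prod(numerators) / sum(denominators)`` on ``[lo, hi)``.

        The rate is taken to be zero outside ``[lo, hi)``.  ``numerators``
        holds one or two piecewise-linear factors; ``denominators`` is a
        list of piecewise-linear functions whose pointwise sum forms the
        denominator (the total size of the receiving side).  The union of
        all component breakpoints defines the simultaneous-linearity
        partition; segment coefficients are recovered by evaluating each
        component at two interior points of the segment, which is exact for
        linear pieces and immune to jump discontinuities at the endpoints
        of a ``zero_outside`` support.
        """
        if not 1 <= len(numerators) <= 2:
            raise ValueError("need one or two numerator factors")
        if not denominators:
            raise ValueError("need at least one denominator component")
        if lo > hi:
            raise ValueError("lo must not exceed hi")
        funcs = list(numerators) + list(denominators)
        cuts = {float(lo)}
        if math.isfinite(hi):
            cuts.add(float(hi))
        else:
            top = max(float(f.breakpoints[-1]) for f in funcs)
            if top > lo:
                cuts.add(top)
        for f in funcs:
            for b in f.breakpoints:
                if lo < float(b) < hi:
                    cuts.add(float(b))
        cuts = sorted(cuts)

        bounds = list(cuts) + [INFINITY]
        coeffs = []

        def linear_on(f, q1, q2):
            f1, f2 = f(q1), f(q2)
            slope = (f2 - f1) / (q2 - q1)
            return f1 - slope * q1, slope

        def seg_coeffs(q1, q2):
            if len(numerators) == 2:
                a1, b1 = linear_on(numerators[0], q1, q2)
                a2, b2 = linear_on(numerators[1], q1, q2)
            else:
                a1, b1 = linear_on(numerators[0], q1, q2)
                a2, b2 = 1.0, 0.0
            if (a1 == 0.0 and b1 == 0.0) or (a2 == 0.0 and b2 == 0.0):
                return (0.0, 0.0, 0.0, 0.0, 1.0, 0.0)
            dens = [linear_on(d, q1, q2) for d in denominators]
            a3 = sum(a for a, _ in dens)
            b3 = sum(b for _, b in dens)
            if a3 + b3 * q1 <= 0.0 or a3 + b3 * q2 <= 0.0:
                raise SingularPopulationError(
                    "population size is nonpositive on an occupied interval"
                )
            return (a1, b1, a2, b2, a3, b3)

        for s0, s1 in zip(cuts[:-1], cuts[1:]):
            w = s1 - s0
            c = seg_coeffs(s0 + w / 3.0, s0 + 2.0 * w / 3.0)
            # guard against a pole at a segment endpoint (nu -> 0 there)
            if c[5] != 0.0 and (c[4] + c[5] * s0 <= 0.0 or c[4] + c[5] * s1 <= 0.0):
                raise SingularPopulationError(
                    "population size touches zero at a segment boundary"
                )
            coeffs.append(c)

        if math.isfinite(hi):
            coeffs.append((0.0, 0.0, 0.0, 0.0, 1.0, 0.0))
        else:
            q = cuts[-1]
            coeffs.append(seg_coeffs(q + 1.0, q + 2.0))
        return cls(bounds, coeffs)

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def _index(self, t: float) -> int:
        i = bisect_right(self.bounds, t) - 1
        return min(max(i, 0), len(self.coeffs) - 1)

    def rate(self, t: float) -> float:
        """Instantaneous event rate at time ``t``."""
        if t < self.bounds[0]:
            return 0.0
        a1, b1, a2, b2, a3, b3 = self.coeffs[self._index(t)]
        return (a1 + b1 * t) * (a2 + b2 * t) / (a3 + b3 * t)

    def segment_at(self, t: float):
        """``(segment_end, rate_is_constant)`` for the segment holding ``t``."""
        i = self._index(t)
        a1, b1, a2, b2, a3, b3 = self.coeffs[i]
        return self.bounds[i + 1], b1 == 0.0 and b2 == 0.0 and b3 == 0.0

    def cumulative(self, t0: float, t1: float) -> float:
        """Integral of the rate over ``[t0, t1]`` (exact per segment)."""
        if t1 < t0:
            raise ValueError("t0 must not exceed t1")
        t0 = max(t0, self.bounds[0])
        if t1 <= t0:
            return 0.0
        total = 0.0
        i = self._index(t0)
        s = t0
        while s < t1:
            e = self.bounds[i + 1]
            u1 = min(e, t1)
            if u1 == INFINITY:
                # constant tail segment
                r = self.rate(s)
                return INFINITY if r > 0.0 else total
            total += _segment_integral(self.coeffs[i], s, u1)
            s = u1
            i += 1
        return total

    def solve(self, t0: float, target: float) -> float:
        """Smallest ``t >= t0`` with ``cumulative(t0, t) == target``.

        Returns ``inf`` when the total hazard beyond ``t0`` never reaches
        ``target``.  A nonpositive target returns ``t0`` itself.
        """
        if target <= 0.0:
            return t0
        t0 = max(t0, self.bounds[0])
        i = self._index(t0)
        s = t0
        remaining = target
        n = len(self.coeffs)
        while i < n:
            e = self.bounds[i + 1]
            c = self.coeffs[i]
            if e == INFINITY:
                a1, b1, a2, b2, a3, b3 = c
                r = (a1 + b1 * s) * (a2 + b2 * s) / (a3 + b3 * s)
                if r <= 0.0:
                    return INFINITY
                return s + remaining / r
            seg = _segment_integral(c, s, e)
            if seg >= remaining:
                if seg == remaining:
                    return e

                def shortfall(x, _c=c, _s=s, _r=remaining):
                    return _segment_integral(_c, _s, x) - _r

                return brentq(shortfall, s, e, xtol=1e-14, rtol=1e-14)
            remaining -= seg
            s = e
            i += 1
        return INFINITY  # pragma: no cover - final segment is unbounded


def integrate_hazard(h: RateIntegral, t0: float, t1: float) -> float:
    """Cumulative hazard of ``h`` over ``[t0, t1]`` (exact analytic integral)."""
    return h.cumulative(t0, t1)


def solve_waiting_time(
    h: RateIntegral, t0: float, u: float, horizon: float = INFINITY
) -> float:
    """Inverse-transform sample of the next event time of hazard ``h``.

    Solves ``int_{t0}^{t} h = -log(1 - u)`` for the smallest such ``t`` and
    returns ``inf`` when the event does not occur before ``horizon``.  The
    result is monotone nondecreasing in ``u``.
    """
    if not 0.0 <= u < 1.0:
        raise ValueError("u must lie in [0, 1)")
    t = h.solve(t0, -math.log1p(-u))
    return t if t <= horizon else INFINITY


def coalescent_hazard(
    nu: PiecewiseLinearFunction,
    n_lineages: int,
    lo: float = 0.0,
    hi: float = INFINITY,
) -> RateIntegral:
    """Coalescent hazard ``C(l, 2) / nu(t)`` for ``l`` exchangeable lineages.

    With fewer than two lineages coalescence is impossible and the hazard
    is identically zero (infinite waiting time).
    """
    if n_lineages < 2:
        return RateIntegral.zero(lo)
    pairs = n_lineages * (n_lineages - 1) / 2.0
    return RateIntegral.from_components(
        [PiecewiseLinearFunction.constant(pairs)], [nu], lo, hi
    )


def migration_hazard(
    m: PiecewiseLinearFunction,
    nu_emigrant: PiecewiseLinearFunction,
    nu_receiving_side: Sequence[PiecewiseLinearFunction],
    lo: float = 0.0,
    hi: float = INFINITY,
) -> RateIntegral:
    """Per-lineage backward migration hazard ``m(t) nu_y(t) / nu_X(t)``.

    ``m`` is the forward migration fraction out of the emigrant clade,
    ``nu_emigrant`` the population function of the single source branch
    ``y`` the lineage jumps to (backward in time), and
    ``nu_receiving_side`` the population functions of all extant branches
    of the clade currently holding the lineage, whose sum ``nu_X`` forms
    the denominator.  When both sides are single branches this reduces to
    the classical backward rate ``m_{b->a}(t) nu_b(t) / nu_a(t)``.
    """
    return RateIntegral.from_components([m, nu_emigrant], nu_receiving_side, lo, hi)
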