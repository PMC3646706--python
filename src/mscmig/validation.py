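"""Independent oracles for the structured-coalescent simulator.

Two cross-checks, deliberately built on different mathematics than the main
simulator:

* :func:`euler_simulate` -- a small-time-step discretization.  In each step
  of length ``dt`` every possible event occurs with probability
  ``rate * dt`` and at most one event can happen per step.  Any decorated
  species tree is supported; accuracy is first order in ``dt``.

* :class:`CTMCModel` -- for two populations with *constant* sizes and
  migration fractions, the lineage-configuration process is a finite-state
  continuous-time Markov chain.  ``exp(Q T)`` gives the configuration
  probabilities at the divergence horizon ``T``; lineages surviving to the
  ancestral population finish under a single-population coalescent whose
  time to the most recent common ancestor is hypoexponential with rates
  ``C(k, 2)/nu``.  Together these yield the exact root-height distribution.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.linalg import expm

from .demographics import INFINITY, PiecewiseLinearFunction
from .species_model import SpeciesNode, SpeciesTree
from .structured_coalescent import GeneTree, LineageState

__all__ = [
    "CTMCModel",
    "euler_simulate",
    "hypoexponential_cdf",
    "hypoexponential_pdf",
    "ks_compare",
    "root_height_distribution",
    "two_species_island_tree",
]


# ----------------------------------------------------------------------
# Euler-step oracle
# ----------------------------------------------------------------------
def euler_simulate(
    stree: SpeciesTree,
    samples: Union[int, Dict[str, int]],
    dt: float,
    rng: np.random.Generator,
) -> GeneTree:
    """Simulate a gene tree by Bernoulli trials on a fixed time grid.

    Within each step of length ``dt`` every possible event fires with
    probability ``rate(t) * dt``, at most one event per step; an event is
    recorded at the end of its step.  On stretches where all rates are
    constant the number of quiet steps is drawn geometrically, which is
    distributionally identical to stepping one by one.  Raises when the
    per-step total event probability exceeds 1 (``dt`` too large).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    state = LineageState(stree, samples)
    while state.total() > 1:
        _euler_one_event(state, dt, rng)
    return GeneTree(state.single_root())


def _euler_active(state: LineageState):
    """Current events as (kind, x, y, hazard, multiplier) tuples."""
    ep = state.epoch
    items = []
    for b in ep.branches:
        l = state.lineage_count(b)
        if l >= 2:
            items.append(("c", b, None, ep.coal[b], l * (l - 1) / 2.0))
    for x, y, h in ep.migrations:
        l = state.lineage_count(x)
        if l >= 1:
            items.append(("m", x, y, h, float(l)))
    return items


def _euler_apply(state: LineageState, item, time: float, rng) -> None:
    kind, x, y = item[0], item[1], item[2]
    if kind == "c":
        state.apply_coalescence(x, time, rng)
    else:
        state.apply_migration(x, y, time, rng)


def _euler_one_event(state: LineageState, dt: float, rng) -> None:
    """Advance the discretized process until one event fires or an epoch ends."""
    ep = state.epoch
    t = state.t
    items = _euler_active(state)
    if not items:
        state.advance_to_epoch_end()
        return
    while True:
        seg_end = ep.hi
        constant = True
        rates = []
        for item in items:
            h, mult = item[3], item[4]
            e, const = h.segment_at(t)
            seg_end = min(seg_end, e)
            constant = constant and const
            rates.append(mult * h.rate(t))
        total = sum(rates)
        p_total = total * dt
        if p_total > 1.0:
            raise ValueError("dt too large: per-step event probability exceeds 1")
        if constant:
            if p_total <= 0.0:
                t = seg_end  # nothing can happen until the next boundary
            else:
                n_quiet = (
                    INFINITY if seg_end == INFINITY
                    else int(math.floor((seg_end - t) / dt))
                )
                g = int(rng.geometric(p_total))
                if g <= n_quiet:
                    time = t + g * dt
                    k = rng.choice(len(items), p=np.asarray(rates) / total)
                    _euler_apply(state, items[int(k)], time, rng)
                    return
                t = seg_end
        else:
            fired = False
            while t + dt <= seg_end:
                rates = [item[4] * item[3].rate(t) for item in items]
                p_total = sum(rates) * dt
                if p_total > 1.0:
                    raise ValueError(
                        "dt too large: per-step event probability exceeds 1"
                    )
                t += dt
                if rng.random() < p_total:
                    k = rng.choice(
                        len(items), p=np.asarray(rates) / (p_total / dt)
                    )
                    _euler_apply(state, items[int(k)], t, rng)
                    return
            t = seg_end
        if t >= ep.hi:
            state.advance_to_epoch_end()
            return
        state.t = t


# ----------------------------------------------------------------------
# constant-rate two-population CTMC
# ----------------------------------------------------------------------
def _binom2(k: int) -> float:
    return k * (k - 1) / 2.0


def hypoexponential_pdf(x, rates: Sequence[float]) -> np.ndarray:
    """Density of a sum of independent exponentials with distinct rates."""
    lam = np.asarray(rates, dtype=float)
    if lam.size == 0:
        raise ValueError("need at least one rate")
    if len(set(lam)) != lam.size:
        raise ValueError("rates must be distinct")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x >= 0
    for i, li in enumerate(lam):
        w = np.prod([lj / (lj - li) for j, lj in enumerate(lam) if j != i])
        out[pos] += w * li * np.exp(-li * x[pos])
    return out


def hypoexponential_cdf(x, rates: Sequence[float]) -> np.ndarray:
    """CDF of a sum of independent exponentials with distinct rates."""
    lam = np.asarray(rates, dtype=float)
    if lam.size == 0:
        raise ValueError("need at least one rate")
    if len(set(lam)) != lam.size:
        raise ValueError("rates must be distinct")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x >= 0
    total = np.zeros_like(x[pos])
    for i, li in enumerate(lam):
        w = np.prod([lj / (lj - li) for j, lj in enumerate(lam) if j != i])
        total += w * np.exp(-li * x[pos])
    out[pos] = 1.0 - total
    return out


class CTMCModel:
    """Lineage-configuration CTMC for two constant-size island populations.

    States are unordered lineage counts ``(i, j)`` in populations *a* and
    *b* with ``2 <= i + j <= n``, plus one absorbing state for a fully
    coalesced sample.  Coalescences occur at rate ``C(i, 2)/nu_a`` (resp.
    ``C(j, 2)/nu_b``); a lineage in *a* jumps (backward) to *b* at rate
    ``m * nu_b / nu_a`` per lineage, the backward counterpart of forward
    emigration at fraction ``m`` out of *b*, and symmetrically.  Beyond the
    divergence horizon ``T`` the surviving lineages coalesce in the
    ancestral population of constant size ``nu_ancestral``.
    """

    def __init__(
        self,
        n_a: int,
        n_b: int,
        nu_a: float,
        nu_b: float,
        m: float,
        T: float,
        nu_ancestral: float,
        m_ba: Optional[float] = None,
    ):
        if n_a < 0 or n_b < 0 or n_a + n_b < 2:
            raise ValueError("need at least two sampled lineages")
        if min(nu_a, nu_b, nu_ancestral) <= 0:
            raise ValueError("population sizes must be positive")
        self.n_a, self.n_b = n_a, n_b
        self.nu_a, self.nu_b = float(nu_a), float(nu_b)
        self.nu_ancestral = float(nu_ancestral)
        self.m_ab = float(m)          # forward fraction a -> b
        self.m_ba = float(m if m_ba is None else m_ba)
        self.T = float(T)

        n = n_a + n_b
        self.states: List[Tuple[int, int]] = [
            (i, k - i) for k in range(n, 1, -1) for i in range(k, -1, -1)
        ]
        self.absorbing = len(self.states)
        index = {s: q for q, s in enumerate(self.states)}
        dim = len(self.states) + 1
        Q = np.zeros((dim, dim))
        # backward per-lineage jump rates (Eq. for the backward migration rate)
        f_ab = self.m_ba * self.nu_b / self.nu_a  # a -> b, driven by forward b->a
        f_ba = self.m_ab * self.nu_a / self.nu_b
        for (i, j), q in index.items():
            k = i + j
            if i >= 2:
                tgt = self.absorbing if k == 2 else index[(i - 1, j)]
                Q[q, tgt] += _binom2(i) / self.nu_a
            if j >= 2:
                tgt = self.absorbing if k == 2 else index[(i, j - 1)]
                Q[q, tgt] += _binom2(j) / self.nu_b
            if i >= 1:
                Q[q, index[(i - 1, j + 1)]] += i * f_ab
            if j >= 1:
                Q[q, index[(i + 1, j - 1)]] += j * f_ba
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        self.Q = Q
        self._init = index[(n_a, n_b)]
        # eigendecomposition for vectorized state probabilities:
        # p(t) = e_init exp(Qt) = (a0 * exp(w t)) @ V^{-1}
        w, V = np.linalg.eig(Q)
        self._w = w
        self._a0 = np.eye(dim)[self._init] @ V
        self._Vinv = np.linalg.inv(V)

    def transition_matrix(self, t: float) -> np.ndarray:
        """``exp(Q t)`` by scipy matrix exponentiation (reference path)."""
        return expm(self.Q * t)

    def state_probabilities(self, t) -> np.ndarray:
        """Row(s) of ``exp(Q t)`` for the initial configuration, vectorized."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        ew = np.exp(np.outer(t, self._w))
        probs = (self._a0 * ew) @ self._Vinv
        return np.clip(probs.real, 0.0, 1.0)

    def _tail_weights(self) -> Dict[int, float]:
        """P(k lineages remain at T), for k >= 2."""
        pT = self.state_probabilities(self.T)[0]
        out: Dict[int, float] = {}
        for (i, j), q in zip(self.states, range(len(self.states))):
            out[i + j] = out.get(i + j, 0.0) + float(pT[q])
        return out

    def _anc_rates(self, k: int) -> List[float]:
        return [_binom2(r) / self.nu_ancestral for r in range(k, 1, -1)]

    def root_height_cdf(self, h) -> np.ndarray:
        """P(gene-tree root height <= h)."""
        h = np.asarray(h, dtype=float)
        scalar = h.ndim == 0
        h = np.atleast_1d(h)
        out = np.zeros_like(h)
        early = h <= self.T
        if early.any():
            out[early] = self.state_probabilities(h[early])[:, self.absorbing]
        late = ~early
        if late.any():
            pT = self.state_probabilities(self.T)[0]
            acc = np.full(int(late.sum()), float(pT[self.absorbing]))
            for k, wk in self._tail_weights().items():
                if wk > 0:
                    acc += wk * hypoexponential_cdf(h[late] - self.T, self._anc_rates(k))
            out[late] = acc
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out

    def root_height_pdf(self, h) -> np.ndarray:
        """Density of the gene-tree root height."""
        h = np.asarray(h, dtype=float)
        scalar = h.ndim == 0
        h = np.atleast_1d(h)
        out = np.zeros_like(h)
        early = h <= self.T
        if early.any():
            probs = self.state_probabilities(h[early])
            for (i, j), q in zip(self.states, range(len(self.states))):
                if i + j != 2:
                    continue
                rate = 0.0
                if i == 2:
                    rate = 1.0 / self.nu_a
                elif j == 2:
                    rate = 1.0 / self.nu_b
                if rate:
                    out[early] += probs[:, q] * rate
        late = ~early
        if late.any():
            acc = np.zeros(int(late.sum()))
            for k, wk in self._tail_weights().items():
                if wk > 0:
                    acc += wk * hypoexponential_pdf(h[late] - self.T, self._anc_rates(k))
            out[late] = acc
        return float(out[0]) if scalar else out


def root_height_distribution(model: CTMCModel, grid) -> np.ndarray:
    """Density values of the gene-tree root height on a time grid."""
    return model.root_height_pdf(np.asarray(grid, dtype=float))


def two_species_island_tree(
    T: float = 2.0,
    nu_a: float = 1.0,
    nu_b: float = 2.0,
    nu_ancestral: float = 1.0,
    m: float = 0.1,
) -> SpeciesTree:
    """Two-species tree with constant sizes and constant reciprocal migration.

    Species ``a`` and ``b`` diverged ``T`` time units ago; the migration
    fraction is constant at ``m`` in both directions over ``[0, T]``.  The
    companion :class:`CTMCModel` with the same parameters gives the exact
    root-height distribution for samples taken from this tree.
    """
    a = SpeciesNode("a", 0.0)
    b = SpeciesNode("b", 0.0)
    root = SpeciesNode(height=T)
    root.add_child(a)
    root.add_child(b)
    tree = SpeciesTree(root)
    tree.nu[a.index] = PiecewiseLinearFunction.constant(nu_a)
    tree.nu[b.index] = PiecewiseLinearFunction.constant(nu_b)
    tree.nu[root.index] = PiecewiseLinearFunction.constant(nu_ancestral)
    if m > 0:
        band = PiecewiseLinearFunction([0.0, T], [m, m], zero_outside=True)
        tree.add_migration(["a"], ["b"], band, symmetric=True)
    tree.separations[root.index] = (T, T)
    return tree


def ks_compare(sample, cdf) -> Tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic and p-value against ``cdf``."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    res = stats.kstest(sample, cdf)
    return float(res.statistic), float(res.pvalue)
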