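"""Species trees decorated with demographies and migration bands.

A :class:`SpeciesTree` is a rooted ultrametric tree (tips at time 0, node
heights measured backwards from the present) whose branches carry
piecewise-linear scaled population sizes ``nu(t)`` and whose clade pairs may
carry migration decorations: forward emigration fractions ``m(t)`` supported
on a separation interval ``[t_s, t_d]``.

The module also houses the stochastic scenario used throughout the package:
Yule topologies, a reconstructed population-size assignment, and the
gradual-separation decoration in which reciprocal migration between sister
clades starts at fraction ``M`` at divergence and declines linearly to zero
at complete separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .demographics import INFINITY, PiecewiseLinearFunction

__all__ = [
    "GradualSeparationScenario",
    "MigrationDecoration",
    "SpeciesNode",
    "SpeciesTree",
    "assign_constant_populations",
    "assign_gradual_separation",
    "assign_populations",
    "backward_migration_rate",
    "simulate_yule",
    "strong_tree",
    "weak_tree",
]


class SpeciesNode:
    """A node of the species tree; the edge to its parent is a population."""

    __slots__ = ("index", "name", "height", "children", "parent")

    def __init__(self, name: Optional[str] = None, height: float = 0.0):
        self.index: int = -1
        self.name = name
        self.height = float(height)
        self.children: List["SpeciesNode"] = []
        self.parent: Optional["SpeciesNode"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "SpeciesNode") -> None:
        self.children.append(child)
        child.parent = self


class MigrationDecoration:
    """Forward emigration from the ``source`` clade into the ``dest`` clade.

    ``m(t)`` is the fraction of the source side emigrating per unit time.
    Going backward in time, a gene lineage residing in a branch of ``dest``
    jumps into a branch of ``source``; emigrants are distributed among the
    extant destination branches proportionally to their population sizes.
    """

    __slots__ = ("source", "dest", "m")

    def __init__(self, source: Iterable[str], dest: Iterable[str], m: PiecewiseLinearFunction):
        self.source = frozenset(source)
        self.dest = frozenset(dest)
        if self.source & self.dest:
            raise ValueError("source and dest clades must be disjoint")
        self.m = m

    @property
    def support(self) -> Tuple[float, float]:
        if self.m.zero_outside:
            return float(self.m.breakpoints[0]), float(self.m.breakpoints[-1])
        return 0.0, INFINITY


class SpeciesTree:
    """Rooted ultrametric species tree with demographic decorations.

    ``nu`` maps a node index to the piecewise-linear population function of
    the branch *above* that node (for the root, the ancestral population,
    extended indefinitely into the past).  ``migrations`` is a list of
    :class:`MigrationDecoration`; ``separations`` records, for decorated
    divergences, the ``(t_s, t_d)`` separation interval used by the
    weak/strong tree constructions.
    """

    def __init__(self, root: SpeciesNode):
        self.root = root
        self.nodes: List[SpeciesNode] = []
        self._collect(root)
        for i, n in enumerate(self.nodes):
            n.index = i
        self.tips = [n for n in self.nodes if n.is_leaf]
        self._tip_by_name = {n.name: n for n in self.tips}
        if len(self._tip_by_name) != len(self.tips):
            raise ValueError("tip names must be unique")
        self._clades: List[frozenset] = [frozenset()] * len(self.nodes)
        for n in self.nodes:  # postorder: children precede parents
            if n.is_leaf:
                self._clades[n.index] = frozenset([n.name])
            else:
                cl = frozenset()
                for c in n.children:
                    cl |= self._clades[c.index]
                self._clades[n.index] = cl
        self._check_heights()
        self.nu: Dict[int, PiecewiseLinearFunction] = {}
        self.migrations: List[MigrationDecoration] = []
        self.separations: Dict[int, Tuple[float, float]] = {}

    def _collect(self, node: SpeciesNode) -> None:
        for c in node.children:
            self._collect(c)
        self.nodes.append(node)

    def _check_heights(self) -> None:
        for n in self.nodes:
            if n.is_leaf and n.height != 0.0:
                raise ValueError("tips must be at height 0 (ultrametric tree)")
            if n.parent is not None and n.parent.height < n.height:
                raise ValueError("parent height must not be below child height")

    # -- structure queries ---------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.tips)

    def leaf_names(self) -> frozenset:
        return self._clades[self.root.index]

    def tip(self, name: str) -> SpeciesNode:
        return self._tip_by_name[name]

    def clade(self, node: SpeciesNode) -> frozenset:
        """Tip names below (and including) ``node``."""
        return self._clades[node.index]

    def mrca(self, names: Iterable[str]) -> SpeciesNode:
        names = frozenset(names)
        if not names:
            raise ValueError("empty taxon set")
        node = self.tip(next(iter(names)))
        while not names <= self._clades[node.index]:
            node = node.parent
        return node

    def mrca_height(self, names: Iterable[str]) -> float:
        return self.mrca(names).height

    def pair_divergence(self, a: str, b: str) -> float:
        return self.mrca([a, b]).height

    def divergence_heights(self) -> List[float]:
        return sorted({n.height for n in self.nodes if not n.is_leaf})

    def branch_interval(self, node: SpeciesNode) -> Tuple[float, float]:
        hi = node.parent.height if node.parent is not None else INFINITY
        return node.height, hi

    def extant_branches(self, t: float) -> List[SpeciesNode]:
        """Branches (as their lower nodes) alive at time ``t``, in index order."""
        out = []
        for n in self.nodes:
            lo, hi = self.branch_interval(n)
            if lo <= t < hi or (n is self.root and t >= lo):
                out.append(n)
        return out

    # -- decoration -----------------------------------------------------
    def add_migration(
        self,
        source: Iterable[str],
        dest: Iterable[str],
        m: PiecewiseLinearFunction,
        symmetric: bool = False,
    ) -> None:
        """Attach a forward emigration fraction between two disjoint clades."""
        known = self.leaf_names()
        src, dst = frozenset(source), frozenset(dest)
        if not (src <= known and dst <= known):
            raise ValueError("migration clades must be subsets of the tip set")
        self.migrations.append(MigrationDecoration(src, dst, m))
        if symmetric:
            self.migrations.append(MigrationDecoration(dst, src, m))

    def is_fully_decorated(self) -> bool:
        return all(n.index in self.nu for n in self.nodes)

    # -- copies and views -----------------------------------------------
    def copy_topology(self) -> "SpeciesTree":
        """Fresh tree with the same topology, names and heights; no decorations."""
        mapping: Dict[int, SpeciesNode] = {}

        def rec(node: SpeciesNode) -> SpeciesNode:
            new = SpeciesNode(node.name, node.height)
            for c in node.children:
                new.add_child(rec(c))
            mapping[node.index] = new
            return new

        out = SpeciesTree(rec(self.root))
        out._source_map = mapping  # original index -> copied node
        return out

    # -- serialization ----------------------------------------------------
    def to_newick(self, annotate: bool = False) -> str:
        """Newick string; with ``annotate`` population functions are written
        as ``[&nu={t:v,...}]`` comment blocks on each branch."""

        def fmt_nu(idx: int) -> str:
            f = self.nu.get(idx)
            if f is None:
                return ""
            body = ",".join(f"{t:g}:{v:g}" for t, v in zip(f.breakpoints, f.values))
            return f"[&nu={{{body}}}]"

        def rec(node: SpeciesNode) -> str:
            if node.is_leaf:
                core = node.name
            else:
                core = "(" + ",".join(rec(c) for c in node.children) + ")"
            ann = fmt_nu(node.index) if annotate else ""
            if node.parent is None:
                return core + ann
            bl = node.parent.height - node.height
            return f"{core}{ann}:{bl:.12g}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        """Parse an ultrametric newick string (topology and heights only)."""
        import dendropy

        dt = dendropy.Tree.get(data=newick, schema="newick")

        def depth(nd):
            d = 0.0
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            return d

        total = max(depth(lf) for lf in dt.leaf_node_iter())

        def rec(nd) -> SpeciesNode:
            if nd.is_leaf():
                return SpeciesNode(nd.taxon.label if nd.taxon else nd.label, 0.0)
            new = SpeciesNode(height=round(total - depth(nd), 12))
            for c in nd.child_nodes():
                new.add_child(rec(c))
            return new

        return cls(rec(dt.seed_node))


def simulate_yule(
    n_species: int,
    birth_rate: float,
    rng: np.random.Generator,
    names: Optional[Sequence[str]] = None,
) -> SpeciesTree:
    """Sample a Yule (pure-birth) species tree topology with node heights.

    Constructed backward in time: while ``i`` lineages remain the time to
    the next join is Exponential(``birth_rate * i``) and a uniformly random
    pair is joined, which is distributionally identical to the forward
    pure-birth process.  Expected root height is ``sum_{i=2..n} 1/(lambda i)``.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    if not birth_rate > 0:
        raise ValueError("birth rate must be positive")
    if names is None:
        names = [f"s{i + 1}" for i in range(n_species)]
    lineages: List[SpeciesNode] = [SpeciesNode(nm, 0.0) for nm in names]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / (birth_rate * k))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        parent = SpeciesNode(height=t)
        parent.add_child(a)
        parent.add_child(b)
        lineages = [n for q, n in enumerate(lineages) if q not in (i, j)]
        lineages.append(parent)
    return SpeciesTree(lineages[0])


def assign_populations(
    tree: SpeciesTree,
    rng: np.random.Generator,
    tip_mean: float = 0.85,
    sd_log: float = 0.4,
    expansion: float = 0.7,
) -> SpeciesTree:
    """Assign linearly varying population functions to every branch.

    Each tip branch's present-day value is drawn log-normally with
    real-space mean ``tip_mean`` and log-space standard deviation
    ``sd_log``; every branch is linear in time with its older end equal to
    ``expansion`` times its younger end (``expansion < 1`` means
    populations grow toward the present).  An internal branch's
    younger-end value is the mean of its children's older-end values; the
    root population is constant at that mean, extended into the past.
    """
    if not tip_mean > 0:
        raise ValueError("tip_mean must be positive")
    if not 0 < expansion <= 1:
        raise ValueError("expansion must lie in (0, 1]")
    if sd_log < 0:
        raise ValueError("sd_log must be nonnegative")
    mu = math.log(tip_mean) - 0.5 * sd_log * sd_log
    older: Dict[int, float] = {}
    for node in tree.nodes:  # postorder
        if node.is_leaf:
            young = float(rng.lognormal(mu, sd_log)) if sd_log > 0 else tip_mean
        else:
            young = float(np.mean([older[c.index] for c in node.children]))
        if node.parent is None:
            tree.nu[node.index] = PiecewiseLinearFunction([node.height], [young])
        else:
            h0, h1 = node.height, node.parent.height
            old = expansion * young
            if h1 > h0:
                tree.nu[node.index] = PiecewiseLinearFunction([h0, h1], [young, old])
            else:
                tree.nu[node.index] = PiecewiseLinearFunction([h0], [young])
            older[node.index] = old
    return tree


def assign_constant_populations(
    tree: SpeciesTree,
    rng: np.random.Generator,
    mean: float = 0.625,
    spread: float = 0.2,
) -> SpeciesTree:
    """Constant per-branch populations drawn uniformly within ``mean*(1±spread)``."""
    lo, hi = mean * (1.0 - spread), mean * (1.0 + spread)
    for node in tree.nodes:
        tree.nu[node.index] = PiecewiseLinearFunction.constant(float(rng.uniform(lo, hi)))
    return tree


def assign_gradual_separation(
    tree: SpeciesTree,
    M: float,
    S: float,
    yule_rate: float,
    rng: np.random.Generator,
    interval_sd_log: float = 0.25,
    max_redraws: int = 100,
) -> SpeciesTree:
    """Decorate every divergence with a gradual-separation migration band.

    For a divergence at height ``t_d`` the separation interval length ``L``
    is log-normal with real-space mean ``S / (2 lambda)`` (half the expected
    Yule branch length, scaled by ``S``) and log-space standard deviation
    ``interval_sd_log``; ``t_s = max(t_d - L, 0)``.  Complete separation of
    a clade must not postdate (in forward time) the complete separation of
    any descendant divergence, i.e. a child's ``t_s`` may not exceed its
    parent's: offending draws are redrawn up to ``max_redraws`` times, then
    clamped.  The reciprocal migration fraction between the two daughter
    clades is ``m(t) = M (t - t_s) / (t_d - t_s)`` on ``[t_s, t_d]`` and
    zero elsewhere; with ``M = 0`` or ``S = 0`` the tree degenerates to the
    strict multispecies coalescent (``t_s = t_d``, no migration).
    """
    if M < 0 or S < 0:
        raise ValueError("M and S must be nonnegative")
    internals = sorted(
        (n for n in tree.nodes if not n.is_leaf), key=lambda n: -n.height
    )
    t_s_of: Dict[int, float] = {}
    for node in internals:  # root first
        t_d = node.height
        cap = INFINITY
        if node.parent is not None:
            cap = t_s_of[node.parent.index]
        if M == 0 or S == 0:
            t_s = t_d
        else:
            mu = math.log(S / (2.0 * yule_rate)) - 0.5 * interval_sd_log ** 2
            t_s = None
            for _ in range(max_redraws):
                L = float(rng.lognormal(mu, interval_sd_log))
                cand = max(t_d - L, 0.0)
                if cand <= cap:
                    t_s = cand
                    break
            if t_s is None:
                t_s = min(cap, t_d)
        t_s_of[node.index] = t_s
        tree.separations[node.index] = (t_s, t_d)
        if M > 0 and t_s < t_d:
            m = PiecewiseLinearFunction([t_s, t_d], [0.0, M], zero_outside=True)
            c1 = tree.clade(node.children[0])
            c2 = tree.clade(node.children[1])
            tree.add_migration(c1, c2, m, symmetric=True)
    return tree


@dataclass
class GradualSeparationScenario:
    """Study conditions for the gradual-separation simulations.

    Defaults reproduce the package's standard setup: 5-species Yule trees
    at birth rate 0.8, population assignment with expansion factor 0.7 and
    log-space spread 0.4 around a present-day mean of 0.85, separation
    intervals with log-space spread 0.25, and 10 sampled individuals per
    species.
    """

    n_species: int = 5
    samples_per_species: int = 10
    yule_rate: float = 0.8
    tip_mean: float = 0.85
    pop_sd_log: float = 0.4
    expansion: float = 0.7
    interval_sd_log: float = 0.25

    def sample_species_tree(
        self, M: float, S: float, rng: np.random.Generator
    ) -> SpeciesTree:
        tree = simulate_yule(self.n_species, self.yule_rate, rng)
        assign_populations(
            tree, rng, tip_mean=self.tip_mean, sd_log=self.pop_sd_log,
            expansion=self.expansion,
        )
        assign_gradual_separation(
            tree, M, S, self.yule_rate, rng, interval_sd_log=self.interval_sd_log
        )
        return tree


def _extant_branch_of(tree: SpeciesTree, species: str, t: float) -> SpeciesNode:
    node = tree.tip(species)
    while node.parent is not None and node.parent.height <= t:
        node = node.parent
    return node


def backward_migration_rate(
    tree: SpeciesTree, from_species: str, to_species: str, t: float
) -> float:
    """Backward per-lineage rate of a jump from ``from_species`` to ``to_species``.

    Looking back in time, a gene lineage currently in the branch holding
    ``from_species`` traces its ancestry into the branch holding
    ``to_species``.  Decorated forward emigrant flow from the source clade
    is shared among the extant destination branches proportionally to
    their population sizes, so the rate is
    ``m(t) * nu_to(t) / nu_dest_side_total(t)``; with single branches on
    both sides this is the classical ``m_{b->a}(t) nu_b(t) / nu_a(t)``.
    """
    x = _extant_branch_of(tree, from_species, t)
    y = _extant_branch_of(tree, to_species, t)
    if x is y:
        raise ValueError("species are not simultaneously extant at this time")
    extant = tree.extant_branches(t)
    cx, cy = tree.clade(x), tree.clade(y)
    rate = 0.0
    for d in tree.migrations:
        if cx <= d.dest and cy <= d.source:
            mval = d.m(t)
            if mval == 0.0:
                continue
            denom = sum(
                tree.nu[z.index](t) for z in extant if tree.clade(z) <= d.dest
            )
            rate += mval * tree.nu[y.index](t) / denom
    return rate


def weak_tree(tree: SpeciesTree) -> SpeciesTree:
    """Species tree with divergences at the *start* of separation (``t_d``)."""
    return tree.copy_topology()


def strong_tree(tree: SpeciesTree) -> SpeciesTree:
    """Species tree with divergences at *complete* separation (``t_s``)."""
    out = tree.copy_topology()
    mapping = out._source_map
    for node in tree.nodes:
        if not node.is_leaf and node.index in tree.separations:
            mapping[node.index].height = tree.separations[node.index][0]
    out._check_heights()
    return out
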