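"""Gene-tree simulation under the multispecies coalescent with migration.

The simulator proceeds backward from the present.  Between consecutive
species divergences the set of extant species branches is fixed; within
such an *epoch*, one candidate waiting time is drawn per possible event --
a coalescence per species holding at least two gene lineages, and a
backward migration per ordered pair of species with an active migration
decoration -- using exact inverse-transform sampling of the
piecewise-rational hazards.  The smallest candidate is applied and all
candidates are redrawn.  An event falling beyond the next divergence is
rejected: time advances to the divergence, the two daughter species'
lineage sets merge into the ancestral branch, and sampling resumes.  Above
the root the process is a single-population coalescent under the root's
population function, extended indefinitely into the past.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .demographics import INFINITY, PiecewiseLinearFunction, RateIntegral
from .species_model import SpeciesTree

__all__ = [
    "ConfigurationError",
    "GeneNode",
    "GeneTree",
    "LineageState",
    "build_epochs",
    "count_inconsistent_coalescences",
    "count_inconsistent_pairs",
    "count_migrations",
    "event_log",
    "simulate_gene_tree",
]


class ConfigurationError(ValueError):
    """The species tree is not fully decorated for simulation."""


class GeneNode:
    """Node of a gene genealogy.

    ``migrations`` lists the backward-time jumps ``(time, from_species,
    to_species)`` that occurred on the branch from this node toward its
    parent, in increasing time order.
    """

    __slots__ = ("time", "name", "species", "children", "parent", "migrations")

    def __init__(self, time: float, name: Optional[str] = None,
                 species: Optional[str] = None):
        self.time = float(time)
        self.name = name
        self.species = species
        self.children: List["GeneNode"] = []
        self.parent: Optional["GeneNode"] = None
        self.migrations: List[Tuple[float, str, str]] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "GeneNode") -> None:
        self.children.append(child)
        child.parent = self


class GeneTree:
    """Binary gene genealogy with node times and migration annotations."""

    def __init__(self, root: GeneNode):
        self.root = root
        self.nodes: List[GeneNode] = []
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                self.nodes.append(node)
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))
        self.tips = [n for n in self.nodes if n.is_leaf]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def tip_labels(self) -> List[str]:
        return [n.name for n in self.tips]

    def species_partition(self) -> Dict[str, str]:
        """Mapping from tip label to the species it was sampled from."""
        return {n.name: n.species for n in self.tips}

    def to_newick(self, migrations: bool = True) -> str:
        """Newick string with branch lengths; migration events are written
        as ``[&mig={(time,from,to),...}]`` comment blocks, or stripped in
        plain mode (``migrations=False``) for downstream tools."""

        def ann(node: GeneNode) -> str:
            if not migrations or not node.migrations:
                return ""
            body = ",".join(f"({t:.9g},{a},{b})" for t, a, b in node.migrations)
            return f"[&mig={{{body}}}]"

        def rec(node: GeneNode) -> str:
            if node.is_leaf:
                core = node.name
            else:
                core = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.parent is None:
                return core + ann(node)
            return f"{core}{ann(node)}:{node.parent.time - node.time:.12g}"

        return rec(self.root) + ";"


# ----------------------------------------------------------------------
# epochs: per-inter-divergence-interval hazard tables
# ----------------------------------------------------------------------
class _Epoch:
    __slots__ = ("lo", "hi", "branches", "coal", "migrations", "merge_nodes")

    def __init__(self, lo: float, hi: float):
        self.lo = lo
        self.hi = hi
        self.branches: List[int] = []
        self.coal: Dict[int, RateIntegral] = {}
        # (dest_branch_index x, source_branch_index y, per-lineage hazard x->y)
        self.migrations: List[Tuple[int, int, RateIntegral]] = []
        self.merge_nodes: List = []


def build_epochs(stree: SpeciesTree) -> List[_Epoch]:
    """Partition time into inter-divergence epochs with cached hazards.

    For each epoch the table holds one unit-rate coalescent hazard
    ``1/nu_i(t)`` per extant branch (scaled by ``C(l, 2)`` at draw time)
    and one per-lineage backward migration hazard per ordered pair of
    extant branches covered by a decoration whose support intersects the
    epoch.  The final epoch extends above the root to infinity.
    """
    if not stree.is_fully_decorated():
        raise ConfigurationError("every branch needs a population function")
    heights = stree.divergence_heights()
    bounds = [0.0] + heights + [INFINITY]
    unit = PiecewiseLinearFunction.constant(1.0)
    epochs: List[_Epoch] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        ep = _Epoch(lo, hi)
        extant = stree.extant_branches(lo)
        ep.branches = [n.index for n in extant]
        for n in extant:
            ep.coal[n.index] = RateIntegral.from_components(
                [unit], [stree.nu[n.index]], lo, hi
            )
        for d in stree.migrations:
            s_lo, s_hi = d.support
            glo, ghi = max(lo, s_lo), min(hi, s_hi)
            if ghi <= glo:
                continue
            src = [n for n in extant if stree.clade(n) <= d.source]
            dst = [n for n in extant if stree.clade(n) <= d.dest]
            if not src or not dst:
                continue
            denom = [stree.nu[n.index] for n in dst]
            for x in dst:
                for y in src:
                    h = RateIntegral.from_components(
                        [d.m, stree.nu[y.index]], denom, glo, ghi
                    )
                    ep.migrations.append((x.index, y.index, h))
        if math.isfinite(hi):
            ep.merge_nodes = [
                n for n in stree.nodes if not n.is_leaf and n.height == hi
            ]
        epochs.append(ep)
    return epochs


class LineageState:
    """Mutable bookkeeping of which species branch each gene lineage occupies.

    Lineages are held per extant species branch; the total count is
    nonincreasing in (backward) simulation time and the simulation
    terminates when a single lineage remains.
    """

    def __init__(self, stree: SpeciesTree, samples: Union[int, Dict[str, int]]):
        self.stree = stree
        self.epochs = build_epochs(stree)
        self.epoch_index = 0
        self.t = 0.0
        if isinstance(samples, int):
            samples = {n.name: samples for n in stree.tips}
        self.groups: Dict[int, List[GeneNode]] = {}
        for tip in stree.tips:
            k = int(samples.get(tip.name, 0))
            if k < 0:
                raise ValueError("sample counts must be nonnegative")
            if k:
                self.groups[tip.index] = [
                    GeneNode(0.0, name=f"{tip.name}_{i + 1}", species=tip.name)
                    for i in range(k)
                ]
        if self.total() < 1:
            raise ValueError("need at least one sampled lineage")
        self._names = {n.index: (n.name or f"clade{n.index}") for n in stree.nodes}

    @property
    def epoch(self) -> _Epoch:
        return self.epochs[self.epoch_index]

    def total(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def lineage_count(self, branch: int) -> int:
        return len(self.groups.get(branch, ()))

    def advance_to_epoch_end(self) -> None:
        """Jump to the next divergence and merge the daughter species."""
        ep = self.epoch
        if not math.isfinite(ep.hi):
            raise ConfigurationError(
                "cannot advance past the final epoch (zero ancestral rate?)"
            )
        for node in ep.merge_nodes:
            merged: List[GeneNode] = []
            for c in node.children:
                merged.extend(self.groups.pop(c.index, ()))
            if merged:
                self.groups[node.index] = merged
        self.t = ep.hi
        self.epoch_index += 1

    def apply_coalescence(self, branch: int, time: float,
                          rng: np.random.Generator) -> GeneNode:
        lin = self.groups[branch]
        i, j = rng.choice(len(lin), size=2, replace=False)
        a, b = lin[i], lin[j]
        parent = GeneNode(time)
        parent.add_child(a)
        parent.add_child(b)
        self.groups[branch] = [n for q, n in enumerate(lin) if q not in (i, j)]
        self.groups[branch].append(parent)
        self.t = time
        return parent

    def apply_migration(self, dest_branch: int, source_branch: int, time: float,
                        rng: np.random.Generator) -> GeneNode:
        """Backward jump of one lineage out of ``dest_branch`` into ``source_branch``."""
        lin = self.groups[dest_branch]
        i = int(rng.integers(len(lin)))
        lineage = lin.pop(i)
        if not lin:
            del self.groups[dest_branch]
        lineage.migrations.append(
            (time, self._names[dest_branch], self._names[source_branch])
        )
        self.groups.setdefault(source_branch, []).append(lineage)
        self.t = time
        return lineage

    def single_root(self) -> GeneNode:
        (lin,) = [n for v in self.groups.values() for n in v]
        return lin


def simulate_gene_tree(
    stree: SpeciesTree,
    samples: Union[int, Dict[str, int]],
    rng: np.random.Generator,
) -> GeneTree:
    """Simulate one gene genealogy within a decorated species tree.

    ``samples`` is the number of individuals sampled per species (an int
    applied to every species, or a per-species mapping; species with zero
    samples still exist as migration destinations).  Candidate waiting
    times are drawn afresh after every applied event; ties between equal
    minima (a measure-zero event) break toward the earliest entry in the
    fixed enumeration -- coalescences in species order, then migrations in
    ordered-pair order.
    """
    state = LineageState(stree, samples)
    while state.total() > 1:
        ep = state.epoch
        best_t = INFINITY
        best = None
        for b in ep.branches:
            l = state.lineage_count(b)
            if l >= 2:
                pairs = l * (l - 1) / 2.0
                target = -math.log1p(-rng.random()) / pairs
                tt = ep.coal[b].solve(state.t, target)
                if tt < ep.hi and tt < best_t:
                    best_t, best = tt, ("c", b, None)
        for x, y, h in ep.migrations:
            l = state.lineage_count(x)
            if l >= 1:
                target = -math.log1p(-rng.random()) / l
                tt = h.solve(state.t, target)
                if tt < ep.hi and tt < best_t:
                    best_t, best = tt, ("m", x, y)
        if best is None:
            state.advance_to_epoch_end()
            continue
        kind, x, y = best
        if kind == "c":
            state.apply_coalescence(x, best_t, rng)
        else:
            state.apply_migration(x, y, best_t, rng)
    return GeneTree(state.single_root())


# ----------------------------------------------------------------------
# summaries of a simulated genealogy
# ----------------------------------------------------------------------
def count_migrations(g: GeneTree) -> int:
    """Total number of migration events recorded on the genealogy."""
    return sum(len(n.migrations) for n in g.nodes)


def _species_sets(g: GeneTree) -> Dict[int, frozenset]:
    out: Dict[int, frozenset] = {}
    for node in g.nodes:  # postorder
        if node.is_leaf:
            out[id(node)] = frozenset([node.species])
        else:
            acc = frozenset()
            for c in node.children:
                acc |= out[id(c)]
            out[id(node)] = acc
    return out


def count_inconsistent_coalescences(
    g: GeneTree, stree: SpeciesTree, tol: float = 1e-9
) -> int:
    """Coalescences more recent than the species-tree MRCA of their taxa.

    A node is counted when its time predates (is smaller than) the height
    of the species-tree MRCA of the sampled species below its two
    children -- impossible under strict divergence, enabled by migration.
    """
    sets = _species_sets(g)
    count = 0
    for node in g.nodes:
        if node.is_leaf:
            continue
        sp = sets[id(node)]
        if len(sp) < 2:
            continue
        if node.time < stree.mrca_height(sp) - tol:
            count += 1
    return count


def count_inconsistent_pairs(
    g: GeneTree, stree: SpeciesTree, tol: float = 1e-9
) -> int:
    """Species pairs joined by some coalescence before their divergence."""
    sets = _species_sets(g)
    bad = set()
    for node in g.nodes:
        if node.is_leaf:
            continue
        left, right = node.children[0], node.children[1]
        for a in sets[id(left)]:
            for b in sets[id(right)]:
                if a != b and node.time < stree.pair_divergence(a, b) - tol:
                    bad.add(frozenset((a, b)))
    return len(bad)


def event_log(g: GeneTree) -> List[Dict[str, object]]:
    """Flat event table (one row per event), sorted by time."""
    rows: List[Dict[str, object]] = []
    sets = _species_sets(g)
    for node in g.nodes:
        for t, a, b in node.migrations:
            rows.append({"time": t, "type": "migration", "from": a, "to": b})
        if not node.is_leaf:
            rows.append({
                "time": node.time,
                "type": "coalescence",
                "from": ",".join(sorted(sets[id(node)])),
                "to": "",
            })
    rows.sort(key=lambda r: r["time"])
    return rows
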