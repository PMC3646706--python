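"""Species-tree generation, demographic assignment and migration resolution."""

import math

import numpy as np
import pytest

from mscmig.demographics import PiecewiseLinearFunction
from mscmig.species_model import (
    GradualSeparationScenario,
    SpeciesNode,
    SpeciesTree,
    assign_constant_populations,
    assign_gradual_separation,
    assign_populations,
    backward_migration_rate,
    simulate_yule,
    strong_tree,
    weak_tree,
)

PLF = PiecewiseLinearFunction


def cherry(T=2.0, nu_a=1.0, nu_b=2.0, nu_anc=1.0):
    a, b = SpeciesNode("a", 0.0), SpeciesNode("b", 0.0)
    root = SpeciesNode(height=T)
    root.add_child(a)
    root.add_child(b)
    tree = SpeciesTree(root)
    tree.nu[a.index] = PLF.constant(nu_a)
    tree.nu[b.index] = PLF.constant(nu_b)
    tree.nu[root.index] = PLF.constant(nu_anc)
    return tree


class TestYule:
    def test_two_species_mean_height(self, rng):
        lam = 0.8
        hs = [simulate_yule(2, lam, rng).root.height for _ in range(5000)]
        mean, se = np.mean(hs), np.std(hs, ddof=1) / math.sqrt(len(hs))
        assert abs(mean - 1 / (2 * lam)) < 3 * se

    def test_five_species_mean_height(self, rng):
        """Mean root height is sum_{i=2..5} 1/(lambda i) for a Yule tree."""
        lam = 0.8
        hs = [simulate_yule(5, lam, rng).root.height for _ in range(4000)]
        expect = sum(1 / (lam * i) for i in range(2, 6))
        mean, se = np.mean(hs), np.std(hs, ddof=1) / math.sqrt(len(hs))
        assert abs(mean - expect) < 3 * se

    def test_structure(self, rng):
        t = simulate_yule(7, 1.0, rng)
        assert t.n_species == 7
        assert len([n for n in t.nodes if not n.is_leaf]) == 6
        for n in t.nodes:
            if n.parent is not None:
                assert n.parent.height > n.height

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            simulate_yule(1, 1.0, rng)
        with pytest.raises(ValueError):
            simulate_yule(3, 0.0, rng)


class TestAssignPopulations:
    def test_degenerate_draw_is_constant(self, rng):
        t = simulate_yule(4, 0.8, rng)
        assign_populations(t, rng, tip_mean=0.85, sd_log=0.0, expansion=1.0)
        for n in t.nodes:
            f = t.nu[n.index]
            assert np.allclose(f.values, 0.85)

    def test_expansion_ratio(self, rng):
        """Every branch's older end is expansion times its younger end."""
        t = simulate_yule(5, 0.8, rng)
        assign_populations(t, rng, expansion=0.7)
        for n in t.nodes:
            if n.parent is None:
                continue
            f = t.nu[n.index]
            young = f(n.height)
            old = f(n.parent.height)
            assert old == pytest.approx(0.7 * young, rel=1e-9)
            assert young > 0

    def test_tip_lognormal_moments(self, rng):
        vals = []
        for _ in range(3000):
            t = simulate_yule(2, 1.0, rng)
            assign_populations(t, rng, tip_mean=0.85, sd_log=0.4)
            vals.extend(t.nu[tip.index](0.0) for tip in t.tips)
        logs = np.log(vals)
        assert np.var(logs, ddof=1) == pytest.approx(0.16, abs=0.012)
        assert np.mean(vals) == pytest.approx(0.85, abs=0.02)

    def test_constant_assignment_spread(self, rng):
        t = simulate_yule(5, 0.8, rng)
        assign_constant_populations(t, rng, mean=0.625, spread=0.2)
        for n in t.nodes:
            v = t.nu[n.index](n.height)
            assert 0.5 <= v <= 0.75
            assert t.nu[n.index].values.size == 1


class TestGradualSeparation:
    def test_band_shape(self, rng):
        """m rises linearly from 0 at t_s to M at t_d."""
        M, S = 0.5, 0.4
        t = simulate_yule(5, 0.8, rng)
        assign_populations(t, rng)
        assign_gradual_separation(t, M, S, 0.8, rng)
        assert t.migrations  # at least one decorated divergence
        for d in t.migrations:
            t_s, t_d = d.support
            assert d.m(t_d) == pytest.approx(M)
            assert d.m(t_s) == pytest.approx(0.0)
            assert d.m((t_s + t_d) / 2) == pytest.approx(M / 2)
            assert d.m(t_s - 1e-9) == 0.0
            assert d.m(t_d + 1e-9) == 0.0

    def test_no_migration_when_M_zero(self, rng):
        t = simulate_yule(5, 0.8, rng)
        assign_populations(t, rng)
        assign_gradual_separation(t, 0.0, 0.5, 0.8, rng)
        assert t.migrations == []
        for ts, td in t.separations.values():
            assert ts == td

    def test_nesting_constraint(self, rng):
        """A clade's complete separation never predates its parent's."""
        sc = GradualSeparationScenario()
        for _ in range(300):
            t = sc.sample_species_tree(0.5, 0.8, rng)
            for n in t.nodes:
                if n.is_leaf or n.parent is None:
                    continue
                assert t.separations[n.index][0] <= t.separations[n.parent.index][0] + 1e-12

    def test_reciprocal_pairs_share_interval(self, rng):
        t = simulate_yule(5, 0.8, rng)
        assign_populations(t, rng)
        assign_gradual_separation(t, 0.3, 0.3, 0.8, rng)
        seen = {}
        for d in t.migrations:
            key = frozenset((d.source, d.dest))
            seen.setdefault(key, []).append(d.support)
        for supports in seen.values():
            assert len(supports) == 2
            assert supports[0] == supports[1]


class TestWeakStrong:
    def test_strict_divergence_trees_coincide(self, rng):
        sc = GradualSeparationScenario()
        t = sc.sample_species_tree(0.0, 0.5, rng)
        w, s = weak_tree(t), strong_tree(t)
        for nw, ns in zip(w.nodes, s.nodes):
            assert nw.height == ns.height

    def test_strong_below_weak_and_valid(self, rng):
        sc = GradualSeparationScenario()
        for _ in range(300):
            t = sc.sample_species_tree(1.0, 0.5, rng)
            w, s = weak_tree(t), strong_tree(t)
            for nw, ns in zip(w.nodes, s.nodes):
                assert ns.height <= nw.height + 1e-12
                if ns.parent is not None:
                    assert ns.parent.height >= ns.height  # still ultrametric


class TestBackwardMigrationRate:
    def test_two_species_classic(self):
        """f_{a->b} = m_{b->a} nu_b / nu_a for single branches."""
        t = cherry(T=2.0, nu_a=1.0, nu_b=2.0)
        band = PLF([0, 2], [0.1, 0.1], zero_outside=True)
        t.add_migration(["a"], ["b"], band, symmetric=True)
        assert backward_migration_rate(t, "a", "b", 1.0) == pytest.approx(0.2)
        assert backward_migration_rate(t, "b", "a", 1.0) == pytest.approx(0.05)

    def _three_species(self, nu_b1, nu_b2):
        a = SpeciesNode("A", 0.0)
        b1, b2 = SpeciesNode("B1", 0.0), SpeciesNode("B2", 0.0)
        nb = SpeciesNode(height=1.0)
        nb.add_child(b1)
        nb.add_child(b2)
        root = SpeciesNode(height=3.0)
        root.add_child(a)
        root.add_child(nb)
        t = SpeciesTree(root)
        t.nu[a.index] = PLF.constant(1.0)
        t.nu[b1.index] = PLF.constant(nu_b1)
        t.nu[b2.index] = PLF.constant(nu_b2)
        t.nu[nb.index] = PLF.constant(nu_b1 + nu_b2)
        t.nu[root.index] = PLF.constant(1.0)
        band = PLF([0, 3], [0.2, 0.2], zero_outside=True)
        t.add_migration(["A"], ["B1", "B2"], band, symmetric=True)
        return t

    def test_equal_sizes_split_evenly(self):
        """Forward emigrants from A split 50/50 between equal-size B1, B2."""
        t = self._three_species(1.0, 1.0)
        m, nu_A = 0.2, 1.0
        f1 = backward_migration_rate(t, "B1", "A", 0.5)
        f2 = backward_migration_rate(t, "B2", "A", 0.5)
        # forward flow arriving into B_i = backward rate * nu_Bi
        assert f1 * 1.0 == pytest.approx(f2 * 1.0)
        assert f1 * 1.0 == pytest.approx(m * nu_A / 2)

    @pytest.mark.parametrize("nu_b1,nu_b2", [(1.0, 1.0), (0.5, 2.5), (2.0, 0.3)])
    def test_total_flow_as_if_unsplit(self, nu_b1, nu_b2):
        """Total forward flow A -> B1 u B2 equals the flow as if B never split."""
        t = self._three_species(nu_b1, nu_b2)
        m, nu_A = 0.2, 1.0
        flow = sum(
            backward_migration_rate(t, b, "A", 0.5) * nu_b
            for b, nu_b in (("B1", nu_b1), ("B2", nu_b2))
        )
        assert flow == pytest.approx(m * nu_A)
        # and above the B divergence the single-branch rate agrees
        assert backward_migration_rate(t, "B1", "A", 2.0) * (
            nu_b1 + nu_b2
        ) == pytest.approx(m * nu_A)

    def test_cherry_with_equal_split_is_invariant(self):
        """An undivided clade equals a cherry with an equal population split."""
        whole = cherry(T=3.0, nu_a=1.0, nu_b=2.0)
        band = PLF([0, 3], [0.2, 0.2], zero_outside=True)
        whole.add_migration(["a"], ["b"], band, symmetric=True)
        split = self._three_species(1.0, 1.0)
        # per-lineage rate of an A lineage jumping anywhere into the B side
        r_whole = backward_migration_rate(whole, "a", "b", 0.5)
        r_split = backward_migration_rate(split, "A", "B1", 0.5) + \
            backward_migration_rate(split, "A", "B2", 0.5)
        assert r_whole == pytest.approx(r_split)

    def test_not_simultaneously_extant(self):
        t = self._three_species(1.0, 1.0)
        with pytest.raises(ValueError):
            backward_migration_rate(t, "B1", "B2", 2.0)  # merged at height 1


class TestNewick:
    def test_round_trip_topology_and_heights(self, rng):
        t = simulate_yule(5, 0.8, rng)
        s = t.to_newick()
        back = SpeciesTree.from_newick(s)
        assert back.leaf_names() == t.leaf_names()
        for pair, h in (
            ((a.name, b.name), t.pair_divergence(a.name, b.name))
            for a in t.tips for b in t.tips if a.name < b.name
        ):
            assert back.pair_divergence(*pair) == pytest.approx(h, abs=1e-9)

    def test_annotated_newick_mentions_nu(self, rng):
        t = simulate_yule(3, 0.8, rng)
        assign_populations(t, rng)
        assert "&nu=" in t.to_newick(annotate=True)
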