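"""Synthetic-data generator: pure-birth trees, Brownian traits, taxonomies
cut from tree depth, and community assembly with known structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import commphylo as cp
from commphylo import AssemblyScenario


class TestYule:
    def test_two_tips_is_ultrametric_cherry(self):
        phy = cp.simulate_yule(2, seed=1)
        assert phy.n_tips == 2
        depths = [
            sum(nd.edge.length for nd in leaf_path(phy, lf))
            for lf in phy.tree.leaf_node_iter()
        ]
        assert depths[0] == pytest.approx(depths[1])

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999), n=st.integers(3, 50))
    def test_ultrametric_and_bifurcating(self, seed, n):
        phy = cp.simulate_yule(n, seed=seed)
        assert phy.n_tips == n
        assert cp.resolution(phy) == 1.0
        depths = [
            sum(nd.edge.length for nd in leaf_path(phy, lf))
            for lf in phy.tree.leaf_node_iter()
        ]
        assert max(depths) - min(depths) < 1e-9

    def test_crown_age_matches_pure_birth_expectation(self):
        """E[crown age] = sum_{k=2..n} 1/(k*lambda) for the pure-birth
        process observed just before the (n+1)-th speciation."""
        n, lam, reps = 8, 1.5, 600
        ages = [
            cp.simulate_yule(n, birth_rate=lam, seed=s).max_depth()
            for s in range(reps)
        ]
        expected = sum(1 / (k * lam) for k in range(2, n + 1))
        se = np.std(ages, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(ages) - expected) < 4 * se

    def test_same_seed_identical_newick(self):
        a = cp.write_newick(cp.simulate_yule(20, seed=9))
        b = cp.write_newick(cp.simulate_yule(20, seed=9))
        assert a == b

    def test_supports_attached_in_range(self):
        phy = cp.simulate_yule(30, seed=2)
        sup = [nd.support for nd in phy.internal_nodes()]
        assert all(s is not None and 50 <= s <= 100 for s in sup)


def leaf_path(phy, leaf):
    node, path = leaf, []
    while node.parent_node is not None:
        path.append(node)
        node = node.parent_node
    return path


class TestBrownian:
    def test_zero_rate_gives_zero_traits(self):
        phy = cp.simulate_yule(10, seed=3)
        traits = cp.evolve_bm(phy, sigma2=0.0, seed=3)
        assert (traits == 0).all()

    def test_tip_variance_matches_closed_form(self):
        """Var(tip) = sigma2 * depth under Brownian motion from the root."""
        phy = cp.simulate_yule(6, seed=4)
        depth = phy.max_depth()
        sigma2 = 2.0
        tip = sorted(phy.tip_labels)[0]
        values = [
            cp.evolve_bm(phy, sigma2, seed=s)[tip] for s in range(500)
        ]
        assert np.var(values) == pytest.approx(sigma2 * depth, rel=0.2)

    def test_conservation_age_freezes_clades(self):
        """With a conservation age, every clade whose stem crosses that age
        shares a single niche value."""
        phy = cp.simulate_yule(30, seed=5)
        cut = 0.4 * phy.max_depth()
        traits = cp.evolve_bm(phy, 1.0, seed=5, conserve_age=cut)
        ages = phy.node_ages()
        for nd in phy.internal_nodes():
            parent = nd.parent_node
            if parent is not None and ages[nd] < cut <= ages[parent]:
                clade = sorted(cp.Phylogeny.leaf_labels_under(nd))
                assert traits[clade].nunique() == 1

    def test_cherry_tips_more_correlated_than_distant_tips(self):
        phy = cp.simulate_yule(12, seed=6)
        D = cp.patristic_matrix(phy)
        v = D.values + np.where(np.eye(len(D.labels), dtype=bool), np.inf, 0)
        i, j = np.unravel_index(np.argmin(v), v.shape)
        near_a, near_b = D.labels[i], D.labels[j]
        k = int(np.argmax(D.values[i]))
        far_b = D.labels[k]
        reps = np.array(
            [
                cp.evolve_bm(phy, 1.0, seed=s)[[near_a, near_b, far_b]]
                for s in range(300)
            ]
        )
        corr = np.corrcoef(reps.T)
        assert corr[0, 1] > corr[0, 2]


class TestTaxonomy:
    def test_cut_near_tips_every_species_own_genus(self):
        phy = cp.simulate_yule(15, seed=7)
        depth = phy.max_depth()
        tax = cp.synth_taxonomy(phy, (1e-9, 0.5 * depth, 0.8 * depth))
        assert len(tax.groups("genus")) == 15

    def test_cut_above_root_single_order(self):
        phy = cp.simulate_yule(15, seed=7)
        depth = phy.max_depth()
        tax = cp.synth_taxonomy(phy, (0.3 * depth, 0.6 * depth, 2 * depth))
        assert len(tax.groups("order")) == 1

    def test_non_increasing_cuts_rejected(self):
        phy = cp.simulate_yule(8, seed=7)
        with pytest.raises(ValueError):
            cp.synth_taxonomy(phy, (1.0, 1.0, 2.0))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_nestedness_invariant_for_random_cuts(self, seed):
        phy = cp.simulate_yule(25, seed=seed)
        depth = phy.max_depth()
        rng = np.random.default_rng(seed)
        cuts = np.sort(rng.uniform(0.05, 0.95, size=3)) * depth
        if len(set(cuts)) < 3:
            return
        tax = cp.synth_taxonomy(phy, tuple(cuts))
        df = tax.table
        assert (df.groupby("genus")["family"].nunique() == 1).all()
        assert (df.groupby("family")["order"].nunique() == 1).all()
        # ranks coarsen monotonically
        assert len(tax.groups("genus")) >= len(tax.groups("family"))
        assert len(tax.groups("family")) >= len(tax.groups("order"))


class TestAssembly:
    def _scenario(self, mode, sites=6, richness=12, **kw):
        names = [f"s{i}" for i in range(sites)]
        return AssemblyScenario(
            mode=mode,
            richness={s: richness for s in names},
            site_groups={s: "g1" for s in names},
            group_optima={"g1": 0.0},
            **kw,
        )

    def test_richness_respected_and_incidence_binary(self):
        phy = cp.simulate_yule(60, seed=8)
        traits = cp.evolve_bm(phy, 1.0, seed=8)
        comm, assign = cp.assemble(
            phy, traits, self._scenario("filtering", filter_width=0.5), seed=8
        )
        assert all(len(comm.site_species(s)) == 12 for s in comm.sites)
        assert set(assign.mapping.values()) == {"g1"}

    def test_wide_filter_degenerates_to_neutral(self):
        """As w -> infinity every species is equally admissible, so species
        inclusion frequencies approach the uniform rate richness/n."""
        phy = cp.simulate_yule(40, seed=9)
        traits = cp.evolve_bm(phy, 1.0, seed=9)
        names = [f"s{i}" for i in range(150)]
        sc = AssemblyScenario(
            mode="filtering",
            richness={s: 10 for s in names},
            site_groups={s: "g" for s in names},
            group_optima={"g": 0.0},
            filter_width=1e9,
        )
        comm, _ = cp.assemble(phy, traits, sc, seed=9)
        freq = comm.matrix.mean(axis=0)
        assert freq.mean() == pytest.approx(10 / 40)
        # no species grossly over/under selected (binomial sd ~ 0.035)
        assert (freq - 0.25).abs().max() < 5 * np.sqrt(0.25 * 0.75 / 150)

    def test_strong_filter_concentrates_on_near_optimum_species(self):
        phy = cp.simulate_yule(60, seed=10)
        traits = cp.evolve_bm(phy, 1.0, seed=10)
        sc = self._scenario("filtering", sites=30, richness=10,
                            filter_width=0.1 * traits.std())
        comm, _ = cp.assemble(phy, traits, sc, seed=10)
        picked = traits[[sp for s in comm.sites for sp in comm.site_species(s)]]
        assert picked.abs().mean() < traits.abs().mean()

    def test_repulsion_members_respect_min_distance(self):
        phy = cp.simulate_yule(50, seed=12)
        D = cp.patristic_matrix(phy)
        sc = AssemblyScenario(
            mode="repulsion",
            richness={"s0": 10},
            repulsion_quantile=0.75,
        )
        comm, _ = cp.assemble(phy, None, sc, seed=12)
        members = sorted(comm.site_species("s0"))
        sub = D.submatrix(members)
        v = sub + np.where(np.eye(len(members), dtype=bool), np.inf, 0)
        off = D.values + np.where(np.eye(len(D.labels), dtype=bool), np.inf, 0)
        threshold = np.quantile(off.min(axis=1), 0.75)
        assert v.min() > threshold

    def test_infeasible_repulsion_errors_after_retries(self):
        phy = cp.simulate_yule(12, seed=13)
        sc = AssemblyScenario(
            mode="repulsion",
            richness={"s0": 11},
            repulsion_quantile=0.99,
            max_retries=5,
        )
        with pytest.raises(RuntimeError, match="infeasible"):
            cp.assemble(phy, None, sc, seed=13)

    def test_bundle_round_trips_through_files(self, tmp_path):
        bundle = cp.simulate_bundle(n_tips=40, seed=14)
        text = cp.write_newick(bundle["phylogeny"])
        reparsed = cp.read_newick(text)
        assert sorted(reparsed.tip_labels) == sorted(
            bundle["phylogeny"].tip_labels
        )
        assert set(bundle["community"].species) <= set(reparsed.tip_labels)
        assert set(bundle["taxonomy"].species) == set(reparsed.tip_labels)
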