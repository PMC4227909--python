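"""Patristic distances, MPD/MNTD, SES nulls, and comparison statistics.

The SES null is checked against exhaustive subset enumeration (the exact
null) on small pools, and MPD/MNTD against brute-force path enumeration.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import commphylo as cp
from commphylo.structure import DegenerateNullError

from conftest import (
    brute_mntd,
    brute_mpd,
    brute_patristic,
    exhaustive_null,
    make_community,
)


class TestPatristic:
    def test_hand_path_sums(self, balanced4_D):
        D = balanced4_D
        i = {lb: k for k, lb in enumerate(D.labels)}
        assert D.values[i["A"], i["B"]] == pytest.approx(2.0)
        assert D.values[i["A"], i["C"]] == pytest.approx(4.0)
        assert np.all(np.diag(D.values) == 0)

    def test_ultrametric_distances_through_root(self):
        phy = cp.simulate_yule(16, seed=11)
        D = cp.patristic_matrix(phy)
        depth = phy.max_depth()
        # tips in different crown subtrees are 2*depth apart
        root_children = phy.tree.seed_node.child_nodes()
        left = sorted(cp.Phylogeny.leaf_labels_under(root_children[0]))
        right = sorted(cp.Phylogeny.leaf_labels_under(root_children[1]))
        i = {lb: k for k, lb in enumerate(D.labels)}
        assert D.values[i[left[0]], i[right[0]]] == pytest.approx(2 * depth)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_matches_brute_force_path_enumeration(self, seed):
        phy = cp.simulate_yule(8, seed=seed)
        D = cp.patristic_matrix(phy)
        labels = D.labels
        for a in labels:
            for b in labels:
                if a < b:
                    i, j = labels.index(a), labels.index(b)
                    assert D.values[i, j] == pytest.approx(
                        brute_patristic(phy, a, b)
                    )


class TestMetrics:
    def test_mpd_single_pair(self, balanced4_D):
        assert cp.mpd({"A", "B"}, balanced4_D) == pytest.approx(2.0)

    def test_mpd_hand_enumeration(self, balanced4_D):
        assert cp.mpd({"A", "B", "C", "D"}, balanced4_D) == pytest.approx(10 / 3)

    def test_mntd_per_tip_nearest(self, balanced4_D):
        assert cp.mntd({"A", "B", "C"}, balanced4_D) == pytest.approx(8 / 3)

    def test_singleton_rejected(self, balanced4_D):
        with pytest.raises(ValueError):
            cp.mpd({"A"}, balanced4_D)
        with pytest.raises(ValueError):
            cp.mntd({"A"}, balanced4_D)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999), k=st.integers(2, 7))
    def test_brute_force_agreement_and_mntd_le_mpd(self, seed, k):
        phy = cp.simulate_yule(8, seed=seed)
        D = cp.patristic_matrix(phy)
        rng = np.random.default_rng(seed)
        sample = set(rng.choice(D.labels, size=k, replace=False))
        assert cp.mpd(sample, D) == pytest.approx(brute_mpd(sample, D))
        assert cp.mntd(sample, D) == pytest.approx(brute_mntd(sample, D))
        assert cp.mntd(sample, D) <= cp.mpd(sample, D) + 1e-12


class TestSES:
    def test_cherry_sample_exhaustive_oracle(self, balanced4_D):
        """Null over pairs from {A,B,C,D} has mean 10/3, sd sqrt(8/9);
        the cherry {A,B} gives index +sqrt(2) in the exact-null limit."""
        pool = cp.SpeciesPool("all", frozenset("ABCD"))
        res = cp.ses_structure(
            {"A", "B"}, pool, balanced4_D, metric="mpd", n_iter=999, seed=3
        )
        mean, sd, _ = exhaustive_null("ABCD", 2, balanced4_D, "mpd")
        assert mean == pytest.approx(10 / 3)
        assert sd == pytest.approx(math.sqrt(8 / 9))
        mc_se = sd / math.sqrt(999)
        assert abs(res.null_mean - mean) < 3 * mc_se
        assert res.index == pytest.approx(math.sqrt(2), abs=0.15)

    def test_obs_at_null_mean_gives_zero_index(self, balanced4_D):
        pool = cp.SpeciesPool("all", frozenset("ABCD"))
        res = cp.ses_structure(
            {"A", "C"}, pool, balanced4_D, metric="mntd", n_iter=999, seed=3
        )
        # degenerate geometry: not asserting zero, but index must be finite
        assert np.isfinite(res.index)

    @pytest.mark.parametrize("metric", ["mpd", "mntd"])
    def test_exhaustive_enumeration_on_small_pool(self, metric):
        """Monte-Carlo null moments converge to exact subset enumeration."""
        phy = cp.simulate_yule(10, seed=21)
        D = cp.patristic_matrix(phy)
        pool = cp.SpeciesPool("all", frozenset(D.labels))
        sample = set(D.labels[:4])  # C(10,4) = 210 <= 500
        mean, sd, values = exhaustive_null(D.labels, 4, D, metric)
        res = cp.ses_structure(
            sample, pool, D, metric=metric, n_iter=4999, seed=5
        )
        assert abs(res.null_mean - mean) < 3 * sd / math.sqrt(4999)
        assert res.null_sd == pytest.approx(sd, rel=0.10)

    def test_shuffle_and_subset_nulls_agree(self, balanced4_D):
        pool = cp.SpeciesPool("all", frozenset("ABCD"))
        rs = [
            cp.ses_structure(
                {"A", "B"}, pool, balanced4_D, n_iter=2999, seed=8,
                method=method,
            )
            for method in ("shuffle", "subset")
        ]
        assert rs[0].null_mean == pytest.approx(rs[1].null_mean, rel=0.05)

    def test_same_seed_bit_identical(self, balanced4_D):
        pool = cp.SpeciesPool("all", frozenset("ABCD"))
        r1 = cp.ses_structure({"A", "B"}, pool, balanced4_D, seed=42, site="s")
        r2 = cp.ses_structure({"A", "B"}, pool, balanced4_D, seed=42, site="s")
        assert r1 == r2

    def test_pool_equal_sample_is_degenerate(self, balanced4_D):
        pool = cp.SpeciesPool("p", frozenset("AB"))
        with pytest.raises(DegenerateNullError):
            cp.ses_structure({"A", "B"}, pool, balanced4_D, seed=1)

    def test_rank_p_values_use_plus_one_convention(self, balanced4_D):
        pool = cp.SpeciesPool("all", frozenset("ABCD"))
        res = cp.ses_structure({"A", "B"}, pool, balanced4_D, n_iter=999, seed=3)
        n = res.n_iter
        assert res.p_low >= 1 / (n + 1) and res.p_high >= 1 / (n + 1)
        # ties counted into both tails make the sum >= 1 + 1/(n+1)
        assert res.p_low + res.p_high >= 1 + 1 / (n + 1) - 1e-12

    def test_clustered_sample_positive_dispersed_negative(self):
        phy = cp.simulate_yule(32, seed=17)
        D = cp.patristic_matrix(phy)
        pool = cp.SpeciesPool("all", frozenset(D.labels))
        # clustered: all tips of one mid-size clade
        clades = [
            cp.Phylogeny.leaf_labels_under(nd)
            for nd in phy.internal_nodes()
            if 4 <= len(cp.Phylogeny.leaf_labels_under(nd)) <= 8
        ]
        clade = min(clades, key=len)
        res_c = cp.ses_structure(clade, pool, D, metric="mpd", seed=2)
        assert res_c.index > 0
        # dispersed: one tip from each child of the root's children
        spread = set()
        for child in phy.tree.seed_node.child_nodes():
            for grand in child.child_nodes():
                spread.add(sorted(cp.Phylogeny.leaf_labels_under(grand))[0])
        res_d = cp.ses_structure(spread, pool, D, metric="mpd", seed=2)
        assert res_d.index < 0

    def test_scale_invariance_of_index(self, balanced4_D):
        pool = cp.SpeciesPool("all", frozenset("ABCD"))
        D2 = cp.DistanceMatrix(balanced4_D.labels, balanced4_D.values * 7.5)
        r1 = cp.ses_structure({"A", "B"}, pool, balanced4_D, seed=9, site="x")
        r2 = cp.ses_structure({"A", "B"}, pool, D2, seed=9, site="x")
        assert r1.index == pytest.approx(r2.index)
        assert r1.p_high == r2.p_high


class TestStructureTable:
    def _setup(self):
        phy = cp.simulate_yule(40, seed=23)
        D = cp.patristic_matrix(phy)
        comm = make_community(
            {
                f"s{i}": set(
                    np.random.default_rng(i).choice(
                        D.labels, size=8, replace=False
                    )
                )
                for i in range(5)
            }
        )
        pools, site_map = cp.build_pools(comm, mode="island")
        return comm, pools, site_map, D

    def test_cardinality(self):
        comm, pools, site_map, D = self._setup()
        results = cp.structure_table(
            comm, pools, site_map, D, metrics=("mpd", "mntd"), n_iter=199, seed=1
        )
        assert len(results) == 5 * 2

    def test_site_order_does_not_change_results(self):
        comm, pools, site_map, D = self._setup()
        fwd = cp.structure_table(comm, pools, site_map, D, n_iter=199, seed=1)
        shuffled = cp.CommunityTable(comm.matrix.iloc[::-1])
        rev = cp.structure_table(shuffled, pools, site_map, D, n_iter=199, seed=1)
        by_key = {(r.site, r.metric): r for r in rev}
        for r in fwd:
            assert by_key[(r.site, r.metric)] == r


class TestComparisonStats:
    def test_identical_vectors_give_t_zero_p_half(self):
        t, df, p = cp.paired_t_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 0.5)

    def test_closed_form_differences(self):
        # d = {1,2,3}: t = mean/ (sd/sqrt(3)) = 2/(1/sqrt(3))
        t, df, p = cp.paired_t_one_tailed([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * math.sqrt(3))
        assert df == 2
        assert 0 < p < 0.05

    def test_fifteen_pairs_have_df_fourteen(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        _, df, _ = cp.paired_t_one_tailed(x, y)
        assert df == 14

    def test_zero_variance_nonzero_differences_rejected(self):
        with pytest.raises(ValueError):
            cp.paired_t_one_tailed([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_pearson_perfect_and_hand_value(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = cp.pearson(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        r, _ = cp.pearson(x, [-v for v in x])
        assert r == pytest.approx(-1.0)
        # hand computation: x=[1,2,4], y=[1,3,3] -> r = 2/sqrt(7)
        r, _ = cp.pearson([1.0, 2.0, 4.0], [1.0, 3.0, 3.0])
        assert r == pytest.approx(2 / math.sqrt(7))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            cp.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
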