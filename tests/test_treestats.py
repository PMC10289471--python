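"""Topology censuses, skew tests, tree space, traits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from spacephylo import treestats as T
from spacephylo.genealogy import GeneTree
from spacephylo.msc_theory import simulate_kingman_tree


def tree_from(newick, species=None):
    t = GeneTree.from_newick(newick)
    if species is None:
        species = {lab: lab for lab in t.tip_labels}
    t.tip_meta = pd.DataFrame(
        {"label": t.tip_labels, "species": [species[l] for l in t.tip_labels]}
    )
    return t


class TestClassify:
    def test_caterpillar(self):
        t = tree_from("(((A:1,B:1):1,C:2):1,D:3);")
        assert T.classify_topology(t, "ABCD") == "(((AB)C)D)"

    def test_balanced(self):
        t = tree_from("((A:1,C:1):2,(B:1,D:1):2);")
        assert T.classify_topology(t, "ABCD") == "((AC)(BD))"

    def test_label_invariant_under_tip_order(self):
        t1 = tree_from("(((B:1,A:1):1,C:2):1,D:3);")
        t2 = tree_from("(D:3,(C:2,(A:1,B:1):1):1);")
        taxa = "ABCD"
        assert T.classify_topology(t1, taxa) == T.classify_topology(t2, taxa)

    def test_multi_tip_taxa_need_rng(self):
        t = tree_from(
            "((A_0:1,A_1:1):1,B_0:2);",
            species={"A_0": "A", "A_1": "A", "B_0": "B"},
        )
        with pytest.raises(ValueError, match="rng"):
            T.classify_topology(t, ["A", "B"])
        assert (
            T.classify_topology(t, ["A", "B"], np.random.default_rng(0))
            == "(AB)"
        )

    def test_missing_taxon_errors(self):
        t = tree_from("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="no tips"):
            T.classify_topology(t, "ABCD")


class TestCensus:
    def test_identical_trees_form_one_class(self):
        trees = [tree_from("(((A:1,B:1):1,C:2):1,D:3);") for _ in range(100)]
        c = T.census_topologies(trees, "ABCD", outgroup="D")
        assert c.counts == {"(((AB)C)D)": 100}
        assert c.total == 100
        assert c.outgroup_ingroup == 0

    def test_outgroup_ingroup_counted(self):
        trees = [
            tree_from("(((A:1,D:1):1,C:2):1,B:3);"),
            tree_from("(((A:1,B:1):1,C:2):1,D:3);"),
        ]
        c = T.census_topologies(trees, "ABCD", outgroup="D")
        assert c.outgroup_ingroup == 1

    def test_counts_permute_under_relabeling(self):
        newicks = [
            "(((A:1,B:1):1,C:2):1,D:3);",
            "(((A:1,C:1):1,B:2):1,D:3);",
            "(((A:1,B:1):1,C:2):1,D:3);",
        ]
        c1 = T.census_topologies([tree_from(n) for n in newicks], "ABCD")
        swapped = [n.replace("B", "X").replace("C", "B").replace("X", "C")
                   for n in newicks]
        c2 = T.census_topologies([tree_from(n) for n in swapped], "ABCD")
        assert c1.counts["(((AB)C)D)"] == c2.counts["(((AC)B)D)"]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            T.census_topologies([], "ABC")


class TestSkew:
    def census_with(self, na, nb):
        return T.TopologyCensus(
            taxa=("A", "B", "C"),
            counts={"((BC)A)": na, "((AC)B)": nb},
            total=na + nb,
        )

    def test_balanced_counts(self):
        r = T.slatkin_skew_test(self.census_with(50, 50), "((BC)A)", "((AC)B)")
        assert r.skew == 0.5
        assert r.pvalue == 1.0

    def test_seventy_thirty_significant(self):
        r = T.slatkin_skew_test(self.census_with(70, 30), "((BC)A)", "((AC)B)")
        assert r.skew == pytest.approx(0.7)
        # oracle: exact two-sided binomial tail sum
        tail = sum(comb(100, k, exact=True) for k in range(70, 101))
        expected = 2 * tail / 2**100
        assert r.pvalue == pytest.approx(expected, rel=1e-9)
        assert r.pvalue < 1e-3

    def test_swap_maps_skew_to_complement(self):
        a = T.slatkin_skew_test(self.census_with(61, 41), "((BC)A)", "((AC)B)")
        b = T.slatkin_skew_test(self.census_with(61, 41), "((AC)B)", "((BC)A)")
        assert a.skew == pytest.approx(1 - b.skew)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_label_canonicalisation_applies(self):
        r = T.slatkin_skew_test(self.census_with(10, 5), "((CB)A)", "((CA)B)")
        assert (r.n_a, r.n_b) == (10, 5)

    def test_empty_classes_rejected(self):
        with pytest.raises(ValueError):
            T.slatkin_skew_test(self.census_with(0, 0), "((BC)A)", "((AC)B)")


class TestWeightedRF:
    def test_identical_trees_distance_zero(self):
        t = tree_from("((A:1,B:1):1,C:2);")
        u = tree_from("((A:1,B:1):1,C:2);")
        assert T.weighted_rf(t, u) == 0.0

    def test_hand_enumerated_example(self):
        # clades AB and AC contribute 1 each; pendant B and C differ by 1
        t1 = tree_from("((A:1,B:1):1,C:2);")
        t2 = tree_from("((A:1,C:1):1,B:2);")
        assert T.weighted_rf(t1, t2) == pytest.approx(4.0)

    def test_metric_properties_on_random_trees(self):
        rng = np.random.default_rng(0)
        labels = [f"t{i}" for i in range(6)]
        trees = [
            simulate_kingman_tree(6, 100, rng, tip_labels=labels)
            for _ in range(30)
        ]
        for _ in range(100):
            i, j, k = rng.choice(30, size=3, replace=False)
            dij = T.weighted_rf(trees[i], trees[j])
            assert dij == pytest.approx(T.weighted_rf(trees[j], trees[i]))
            assert dij >= 0
            assert dij <= T.weighted_rf(trees[i], trees[k]) + T.weighted_rf(
                trees[k], trees[j]
            ) + 1e-9
        D = T.rf_distance_matrix(trees[:10])
        for a in range(10):
            for b in range(10):
                assert D[a, b] == pytest.approx(
                    T.weighted_rf(trees[a], trees[b])
                )

    def test_mismatched_tips_rejected(self):
        with pytest.raises(ValueError, match="tip sets"):
            T.weighted_rf(
                tree_from("((A:1,B:1):1,C:2);"),
                tree_from("((A:1,B:1):1,D:2);"),
            )


class TestNMDS:
    def test_equilateral_three_points(self):
        D = np.ones((3, 3)) - np.eye(3)
        emb = T.nmds_embed(D, seed=0)
        assert emb.stress < 1e-3
        d01 = np.linalg.norm(emb.coords[0] - emb.coords[1])
        d02 = np.linalg.norm(emb.coords[0] - emb.coords[2])
        assert d01 == pytest.approx(d02, rel=0.05)

    def test_exactly_embeddable_distances_have_tiny_stress(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = T.nmds_embed(D, seed=1)
        assert emb.stress < 1e-3

    def test_same_seed_reproduces_coordinates(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        a = T.nmds_embed(D, seed=7)
        b = T.nmds_embed(D, seed=7)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            T.nmds_embed(D, seed=0)


class TestCentroidDisplacement:
    def embedding(self, coords, labels):
        coords = np.asarray(coords, dtype=float)
        return T.TreeSpaceEmbedding(
            coords=coords - coords.mean(axis=0), stress=0.0, labels=labels
        )

    def test_single_group_displacement_zero(self):
        e = self.embedding([[0, 0], [2, 0], [1, 2]], ["g", "g", "g"])
        assert T.centroid_displacement(e, "g") == pytest.approx(0.0)

    def test_mirrored_groups_have_equal_displacement(self):
        e = self.embedding(
            [[1, 0], [2, 0], [-1, 0], [-2, 0]], ["a", "a", "b", "b"]
        )
        assert T.centroid_displacement(e, "a") == pytest.approx(
            T.centroid_displacement(e, "b")
        )

    def test_unknown_group_rejected(self):
        e = self.embedding([[0, 0], [1, 1]], ["a", "a"])
        with pytest.raises(ValueError):
            T.centroid_displacement(e, "b")


class TestTopologyDistanceRegression:
    def coords(self):
        return pd.DataFrame(
            {
                "species": ["A", "B", "C", "D"],
                "x": [0.0, 4.0, 8.0, 12.0],
                "y": [0.0, 0.0, 0.0, 0.0],
            }
        )

    def census(self, n_a, n_b, n_c, n_conc):
        counts = {
            "(((AD)B)C)": n_a,
            "(((BD)A)C)": n_b,
            "(((CD)A)B)": n_c,
            "(((AB)C)D)": n_conc,
        }
        counts = {k: v for k, v in counts.items() if v}
        return T.TopologyCensus(
            taxa=("A", "B", "C", "D"),
            counts=counts,
            total=sum(counts.values()),
            outgroup="D",
        )

    def test_equal_proportions_give_zero_slope(self):
        slope, p = T.topology_distance_regression(
            self.census(10, 10, 10, 70), self.coords(), "D"
        )
        assert slope == pytest.approx(0.0)
        assert p == 1.0

    def test_linear_decrease_with_distance_is_negative(self):
        # proportions fall linearly as the sister sits farther from D
        slope, p = T.topology_distance_regression(
            self.census(5, 25, 45, 125), self.coords(), "D"
        )
        assert slope < 0
        assert p < 0.05

    def test_too_few_classes_rejected(self):
        census = T.TopologyCensus(
            taxa=("A", "B", "D"), counts={"((AB)D)": 5}, total=5
        )
        with pytest.raises(ValueError, match=">= 3"):
            T.topology_distance_regression(census, self.coords(), "D")


class TestGeographicMonophyly:
    def test_full_group_trivially_monophyletic(self):
        trees = [tree_from("((A_0:1,A_1:1):1,B_0:2);") for _ in range(3)]
        r = T.geographic_monophyly(
            trees, {"all": ["A_0", "A_1", "B_0"]}
        )
        assert r["all"] == 1.0

    def test_hand_counted_fraction(self):
        trees = [
            tree_from("(((A_0:1,A_1:1):1,B_0:2):1,B_1:3);"),  # A mono
            tree_from("(((A_0:1,B_0:1):1,A_1:2):1,B_1:3);"),  # A not mono
            tree_from("((A_0:1,A_1:1):2,(B_0:1,B_1:1):2);"),  # A mono
            tree_from("(((A_0:1,A_1:1):1,B_1:2):1,B_0:3);"),  # A mono
        ]
        r = T.geographic_monophyly(trees, {"A": ["A_0", "A_1"]})
        assert r["A"] == pytest.approx(0.75)

    def test_singleton_group_warns(self):
        trees = [tree_from("((A_0:1,A_1:1):1,B_0:2);")]
        with pytest.warns(UserWarning, match="singleton"):
            r = T.geographic_monophyly(trees, {"one": ["B_0"]})
        assert r["one"] == 1.0


class TestBinaryTraits:
    def balanced_tree(self, depth=1.0):
        return tree_from(
            f"((a:{depth},b:{depth}):{depth},(c:{depth},d:{depth}):{depth});"
        )

    def test_negligible_rate_copies_root_state(self):
        t = self.balanced_tree()
        tm = T.simulate_binary_traits(t, 50, 1e-9, np.random.default_rng(0))
        assert np.all(tm.matrix == tm.matrix[0])

    def test_saturating_rate_gives_fair_coins(self):
        t = self.balanced_tree(depth=1000.0)
        tm = T.simulate_binary_traits(t, 4000, 5.0, np.random.default_rng(1))
        freq = tm.matrix.mean()
        assert freq == pytest.approx(0.5, abs=0.03)

    def test_two_tip_divergence_closed_form(self):
        rate, tdiv = 0.3, 1.0
        t = tree_from(f"(a:{tdiv},b:{tdiv});")
        tm = T.simulate_binary_traits(t, 10_000, rate, np.random.default_rng(2))
        p_diff = np.mean(tm.states("a") != tm.states("b"))
        expected = 0.5 * (1 - math.exp(-4 * rate * tdiv))
        assert p_diff == pytest.approx(expected, abs=0.02)

    def test_supporting_trait_counting(self):
        tm = T.TraitMatrix(
            matrix=np.array(
                [[0, 1, 1], [0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.uint8
            ),
            tips=["a", "b", "c", "d"],
            rate=1.0,
        )
        # trait 0 (all zero) supports nothing; trait 1 is a strict
        # synapomorphy of {a, b}; trait 2 marks {a, c}
        assert T.count_supporting_traits(tm, ["a", "b"]) == 1
        assert T.count_supporting_traits(tm, ["a", "c"]) == 1
        assert T.count_supporting_traits(tm, ["a", "d"]) == 0
        with pytest.raises(ValueError):
            T.count_supporting_traits(tm, [])

    def test_location_clade_supported_more_than_random_tips(self):
        # a long stem under a location cluster accumulates synapomorphies
        rng = np.random.default_rng(3)
        newick = (
            "(((L_0:0.1,L_1:0.1):2.9,(M_0:1.5,M_1:1.5):1.5):1.0,"
            "(N_0:2.0,N_1:2.0):2.0);"
        )
        t = tree_from(newick)
        wins = 0
        for s in range(10):
            tm = T.simulate_binary_traits(
                t, 40, 0.25, np.random.default_rng(100 + s)
            )
            clustered = T.count_supporting_traits(tm, ["L_0", "L_1"])
            random_tips = T.count_supporting_traits(tm, ["L_0", "M_0"])
            wins += clustered >= random_tips
        assert wins >= 8
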