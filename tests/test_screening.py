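"""Whole-network screening, synergy ratios, distances, trees, drug graph."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import drugsynergy as ds
from drugsynergy.blocking_oracle import SynergyProfile
from drugsynergy.screening import OUTCOMES, profile_label


def make_profile(drugs, Y, universe=("a", "b", "c", "d", "e")):
    return SynergyProfile(
        combination=frozenset(drugs), Y=frozenset(Y), universe=tuple(universe)
    )


class TestSingleDrugEffects:
    def test_upstream_drug_blocks_whole_toy(self, toy):
        model, catalog, _ = toy
        effects = ds.single_drug_effects(model, catalog)
        assert effects["drug_v2"] == frozenset(model.parents())

    def test_no_target_drug_blocks_nothing_new(self, toy_model):
        catalog = ds.DrugCatalog()
        assert ds.single_drug_effects(toy_model, catalog) == {}


@pytest.fixture(scope="module")
def toy_rows(toy):
    model, catalog, _ = toy
    return ds.screen_all_objectives(model, catalog)


class TestScreen:
    def test_one_row_per_reaction(self, toy_rows, toy_model):
        assert [r.objective for r in toy_rows] == toy_model.parents()

    def test_partition_into_outcome_classes(self, toy_rows):
        for row in toy_rows:
            assert row.baseline_blocked or row.error or row.outcome in OUTCOMES

    def test_objective_v10_is_more_selective(self, toy_rows):
        """The pair {v4,v7} (sigma 3) beats the only single drug v2 (sigma 9)."""
        row = {r.objective: r for r in toy_rows}["v10"]
        assert row.outcome == "more_selective"
        assert row.best_single_drug == "drug_v2" and row.best_single_sigma == 9.0
        assert row.multi_solution.used_drugs == {"drug_v4", "drug_v7"}
        assert row.multi_solution.sigma_oracle == 3.0

    def test_classification_agrees_with_oracle_sigmas(self, toy, toy_rows):
        model, catalog, _ = toy
        for row in toy_rows:
            if row.outcome in ("more_selective", "less_selective"):
                multi = row.multi_solution.sigma_oracle
                single = ds.side_effect(
                    model, catalog, [row.best_single_drug], row.objective
                ).sigma
                assert single == row.best_single_sigma
                assert (multi < single) == (row.outcome == "more_selective")

    def test_baseline_blocked_reaction_excluded(self, toy):
        model, catalog, _ = toy
        dead = model.with_zeroed({"v6"})
        rows = ds.screen_all_objectives(dead, catalog, objectives=["v6"])
        assert rows[0].baseline_blocked and rows[0].outcome is None

    def test_table_export_columns(self, toy_rows):
        table = ds.screen_to_table(toy_rows)
        assert {"objective", "outcome", "drugs", "side_effect", "ratio"} <= set(
            table.columns
        )
        assert len(table) == len(toy_rows)


class TestSynergyRatio:
    @pytest.mark.parametrize(
        "n_synergy,sigma,expected",
        [
            (5, 11.0, 45.4),
            (91, 363.8, 25.0),
            (91, 377.7, 24.0),
            (91, 390.6, 23.2),
            (6, 116.0, 5.1),
            (1, 84.7, 1.1),
            (17, 118.2, 14.3),
            (0, 5.0, 0.0),
        ],
    )
    def test_percentage_truncated_to_one_decimal(self, n_synergy, sigma, expected):
        assert ds.synergy_ratio(n_synergy, sigma) == pytest.approx(expected)

    def test_zero_sigma_undefined(self):
        with pytest.raises(ValueError):
            ds.synergy_ratio(1, 0.0)


class TestDistanceMatrix:
    def test_identical_profiles_at_distance_zero(self):
        p = make_profile(["d1", "d2"], ["a", "b"])
        q = make_profile(["d3", "d4"], ["a", "b"])
        assert ds.distance_matrix([p, q])[0, 1] == 0.0

    def test_disjoint_sets_at_distance_one(self):
        p = make_profile(["d1", "d2"], ["a"])
        q = make_profile(["d3", "d4"], ["b"])
        assert ds.distance_matrix([p, q])[0, 1] == 1.0

    def test_jaccard_formula(self):
        p = make_profile(["d1", "d2"], ["a", "b"])
        q = make_profile(["d3", "d4"], ["b", "c"])
        assert ds.distance_matrix([p, q])[0, 1] == pytest.approx(2 / 3)

    def test_empty_set_conventions(self):
        e1 = make_profile(["d1", "d2"], [])
        e2 = make_profile(["d3", "d4"], [])
        p = make_profile(["d5", "d6"], ["a"])
        D = ds.distance_matrix([e1, e2, p])
        assert D[0, 1] == 0.0 and D[0, 2] == 1.0

    def test_hamming_counts_vector_disagreements(self):
        p = make_profile(["d1", "d2"], ["a", "b"])
        q = make_profile(["d3", "d4"], ["b", "c"])
        assert ds.distance_matrix([p, q], metric="hamming")[0, 1] == pytest.approx(2 / 5)

    @settings(max_examples=50, deadline=None)
    @given(
        sets=st.lists(
            st.sets(st.sampled_from(["a", "b", "c", "d", "e"])), min_size=3, max_size=6
        )
    )
    def test_metric_axioms(self, sets):
        """Jaccard distances: zero diagonal, symmetry, triangle inequality."""
        profiles = [make_profile([f"x{i}", f"y{i}"], s) for i, s in enumerate(sets)]
        D = ds.distance_matrix(profiles)
        n = len(profiles)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestClusterTree:
    def test_two_profiles_make_a_cherry(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        newick = ds.cluster_tree(D, ["p1", "p2"])
        assert newick.startswith("(") and "p1" in newick and "p2" in newick

    @pytest.mark.parametrize("method", ["average", "nj"])
    def test_close_pair_are_sisters(self, method):
        D = np.array(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        newick = ds.cluster_tree(D, ["p1", "p2", "out"], method=method)
        import io

        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(newick))
        p1 = tree.find("p1")
        assert {t.name for t in p1.parent.children if t.name} >= {"p1", "p2"}

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            ds.cluster_tree(np.zeros((1, 1)), ["only"])

    def test_flat_clusters_split_far_groups(self):
        D = np.array(
            [[0.0, 0.1, 0.9, 0.9],
             [0.1, 0.0, 0.9, 0.9],
             [0.9, 0.9, 0.0, 0.1],
             [0.9, 0.9, 0.1, 0.0]]
        )
        classes = ds.flat_clusters(D, ["a", "b", "c", "d"], threshold=0.5)
        assert classes["a"] == classes["b"] != classes["c"] == classes["d"]


class TestDrugProximityNetwork:
    def test_pair_solution_gives_single_edge(self):
        G = ds.drug_proximity_network([make_profile(["d1", "d2"], ["a"])])
        assert list(G.edges) == [("d1", "d2")]
        assert G["d1"]["d2"]["weight"] == 1

    def test_triple_solution_gives_triangle(self):
        G = ds.drug_proximity_network([make_profile(["d1", "d2", "d3"], ["a", "b"])])
        assert G.number_of_edges() == 3

    def test_shared_drug_connects_components(self):
        G = ds.drug_proximity_network(
            [make_profile(["d1", "d2"], ["a"]), make_profile(["d2", "d3"], ["b"])]
        )
        assert G.number_of_nodes() == 3
        import networkx as nx

        assert nx.is_connected(G)

    def test_node_size_attribute_from_catalog(self, toy):
        model, catalog, _ = toy
        G = ds.drug_proximity_network(
            [make_profile(["drug_v4", "drug_v7"], ["v10"])], catalog
        )
        assert G.nodes["drug_v4"]["n_targets"] == 1

    def test_label_is_sorted_combination(self):
        assert profile_label(make_profile(["b", "a"], [])) == "a+b"
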