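"""Selective (two-network) inhibition and the additional-target screen."""

import pytest

import drugsynergy as ds
from drugsynergy.fixtures import _raw_from_reactions


def _degenerate_pair(toy):
    model, catalog, objective = toy
    pair = ds.NetworkPair(
        target_model=model,
        reference_model=model,
        catalog_target=catalog,
        catalog_reference=catalog,
        correspondence={r: r for r in model.parents()},
    )
    return pair, objective


@pytest.fixture(scope="module")
def asymmetric_pair():
    """Target cell has an extra pathway (x1 -> x2) feeding the objective;
    the reference cell lacks it entirely, so the drug on x2 is invisible
    there except through its beta weight."""
    target_raw = _raw_from_reactions(
        [
            ("u", {"A": 1.0}, 0.0, 10.0),
            ("x1", {"A": -1.0, "T": 1.0}, 0.0, 10.0),
            ("x2", {"T": -1.0, "G": 1.0}, 0.0, 10.0),
            ("growth", {"G": -1.0}, 0.0, 10.0),
            ("house", {"A": -1.0}, 0.0, 10.0),
        ]
    )
    reference_raw = _raw_from_reactions(
        [
            ("u", {"A": 1.0}, 0.0, 10.0),
            ("house", {"A": -1.0}, 0.0, 10.0),
        ]
    )
    target = ds.split_reversible(target_raw)
    reference = ds.split_reversible(reference_raw)
    records = [
        ds.DrugRecord(
            "d_x2", direct_target_reactions=frozenset({"x2"}), n_nonmetabolic_targets=1
        ),
        ds.DrugRecord("d_house", direct_target_reactions=frozenset({"house"})),
    ]
    cat_t = ds.build_catalog(records, target, beta_bar=2.0)
    cat_r = ds.build_catalog(records, reference, beta_bar=2.0)
    corr = {"u": "u", "house": "house"}
    return ds.NetworkPair(target, reference, cat_t, cat_r, corr)


class TestSolveSelective:
    def test_degenerate_pair_reproduces_single_network(self, toy):
        pair, objective = _degenerate_pair(toy)
        selective = ds.solve_selective(pair, objective)
        single = ds.solve_optimal_combination(*toy)
        assert selective.status == "optimal"
        assert selective.used_drugs == single.used_drugs
        assert selective.sigma_oracle == single.sigma_oracle

    def test_target_only_drug_spares_reference(self, asymmetric_pair):
        sol = ds.solve_selective(asymmetric_pair, "growth")
        assert sol.status == "optimal"
        assert sol.used_drugs == {"d_x2"}
        # no reference reaction stops; only the beta penalty remains
        assert sol.oracle_report.stopped_reactions == frozenset()
        assert sol.sigma_oracle == pytest.approx(2.0)  # beta_bar * 1 nonmetabolic

    def test_objective_without_correspondence_counts_everything(self, toy):
        model, catalog, objective = toy
        pair = ds.NetworkPair(
            target_model=model,
            reference_model=model,
            catalog_target=catalog,
            catalog_reference=catalog,
            correspondence={},  # objective has no reference twin
        )
        sol = ds.solve_selective(pair, objective)
        single = ds.solve_optimal_combination(model, catalog, objective)
        assert sol.used_drugs == single.used_drugs
        # the blocked objective itself now counts on the reference side
        assert sol.sigma_oracle == single.sigma_oracle + 1

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_degenerate_random_pairs_match_single_network(self, seed):
        model, catalog, objective = ds.random_instance(
            ds.RandomInstanceSpec(seed=seed)
        )
        pair = ds.NetworkPair(
            target_model=model,
            reference_model=model,
            catalog_target=catalog,
            catalog_reference=catalog,
            correspondence={r: r for r in model.parents()},
        )
        selective = ds.solve_selective(pair, objective)
        single = ds.solve_optimal_combination(model, catalog, objective)
        assert selective.status == single.status
        if single.status == "optimal":
            assert selective.sigma_oracle == pytest.approx(single.sigma_oracle)


class TestEnumerateSelective:
    def test_reference_sigma_nondecreasing(self, toy):
        pair, objective = _degenerate_pair(toy)
        sols = ds.enumerate_selective(pair, objective)
        sigmas = [s.sigma_milp for s in sols]
        assert len(sols) == 2
        assert sigmas == sorted(sigmas)

    def test_max_solutions_zero(self, toy):
        pair, objective = _degenerate_pair(toy)
        assert ds.enumerate_selective(pair, objective, max_solutions=0) == []


class TestAdditionalTargetScreen:
    def test_deletion_lethal_candidate_flagged(self, asymmetric_pair):
        rows = ds.additional_target_screen(
            asymmetric_pair, "growth", candidate_reactions=["x1"]
        )
        assert rows[0].flag == "deletion_lethal" and rows[0].solution is None

    def test_irrelevant_candidate_keeps_baseline_solution(self, asymmetric_pair):
        rows = ds.additional_target_screen(
            asymmetric_pair, "growth", candidate_reactions=["house"]
        )
        assert rows[0].flag == "unchanged"
        assert rows[0].solution.used_drugs == {"d_x2"}
        assert rows[0].deleted_in_reference  # house exists in both networks

    def test_candidate_without_correspondence_flagged(self, asymmetric_pair):
        rows = ds.additional_target_screen(
            asymmetric_pair, "growth", candidate_reactions=["x2"]
        )
        assert not rows[0].deleted_in_reference

    def test_new_inhibition_via_additional_target(self):
        """Two parallel pathways feed the objective; drugs only reach one of
        them, so no drug set blocks the objective -- until the undruggable
        branch is deleted as an additional target."""
        raw = _raw_from_reactions(
            [
                ("u", {"A": 1.0}, 0.0, 10.0),
                ("p1", {"A": -1.0, "G": 1.0}, 0.0, 10.0),
                ("p2", {"A": -1.0, "G": 1.0}, 0.0, 10.0),
                ("growth", {"G": -1.0}, 0.0, 10.0),
                ("house", {"A": -1.0}, 0.0, 10.0),
            ]
        )
        model = ds.split_reversible(raw)
        records = [ds.DrugRecord("d_p1", direct_target_reactions=frozenset({"p1"}))]
        catalog = ds.build_catalog(records, model, beta_bar=0.0)
        pair = ds.NetworkPair(
            target_model=model,
            reference_model=model,
            catalog_target=catalog,
            catalog_reference=catalog,
            correspondence={r: r for r in model.parents()},
        )
        baseline = ds.solve_selective(pair, "growth")
        assert baseline.status == "infeasible"
        rows = ds.additional_target_screen(
            pair, "growth", candidate_reactions=["p2", "house"]
        )
        by_cand = {r.candidate: r for r in rows}
        assert by_cand["p2"].flag == "new_inhibition"
        assert by_cand["p2"].solution.used_drugs == {"d_p1"}
        assert by_cand["house"].flag == "no_solution"

    def test_deleting_never_unblocks(self, toy):
        """Removing a reaction can only grow the blocked set."""
        model, catalog, _ = toy
        before = ds.blocked_reactions(model, catalog, ["drug_v4"])
        after = ds.blocked_reactions(
            model.with_zeroed({"v8"}), catalog, ["drug_v4"]
        )
        assert before <= after
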