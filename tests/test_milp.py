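"""The duality-reformulated MILP: assembly, optima, enumeration, verification."""

import pytest

import drugsynergy as ds
from drugsynergy.blocking_oracle import BruteForceSearcher


class TestBuild:
    def test_toy_variable_counts(self, toy):
        model, catalog, objective = toy
        inst = ds.build_milp(model, catalog, objective)
        # binaries: one y per reaction plus one d per drug; one z per
        # (target reaction, drug) coupling
        assert inst.n_binaries == 10 + 3
        assert inst.n_z == 3
        # continuous: v and lambda per reaction, mu per metabolite, delta+z
        assert inst.prog.n_vars == 2 * 10 + 5 + 2 * 3 + 13

    def test_multi_target_drug_makes_two_couplings(self, toy_model):
        records = [
            ds.DrugRecord("wide", direct_target_reactions=frozenset({"v4", "v7"}))
        ]
        catalog = ds.build_catalog(records, toy_model, beta_bar=0.0)
        inst = ds.build_milp(toy_model, catalog, "v10")
        assert inst.n_z == 2 and len(inst.delta) == 2

    def test_forbidden_cut_excludes_set_and_supersets(self, toy):
        model, catalog, objective = toy
        sol = ds.solve_optimal_combination(
            model, catalog, objective,
            forbidden_cuts=[{"drug_v4", "drug_v7"}],
        )
        assert sol.status == "optimal"
        assert not {"drug_v4", "drug_v7"} <= sol.used_drugs
        assert sol.used_drugs == {"drug_v2"}

    def test_baseline_blocked_objective_is_degenerate(self, toy):
        model, catalog, _ = toy
        dead = model.with_zeroed({"v6"})
        with pytest.raises(ds.DegenerateInstanceError):
            ds.build_milp(dead, catalog, "v6")

    def test_lp_export_mentions_all_blocks(self, toy):
        model, catalog, objective = toy
        text = ds.build_milp(model, catalog, objective).to_lp_string()
        for token in ["Minimize", "strongdual", "dual_v10", "Binary", "d_drug_v2"]:
            assert token in text


class TestSolve:
    def test_toy_optimum_is_the_synergistic_pair(self, toy_solution):
        assert toy_solution.status == "optimal"
        assert toy_solution.used_drugs == {"drug_v4", "drug_v7"}
        assert toy_solution.sigma_oracle == 3.0

    def test_duality_certificate_on_toy(self, toy_solution):
        assert toy_solution.inner_max < ds.MilpConfig().epsilon

    def test_unblockable_objective_infeasible(self, toy_model):
        # a drug far downstream cannot stop the uptake reaction v1
        records = [ds.DrugRecord("d9", direct_target_reactions=frozenset({"v9"}))]
        catalog = ds.build_catalog(records, toy_model, beta_bar=0.0)
        sol = ds.solve_optimal_combination(toy_model, catalog, "v1")
        assert sol.status == "infeasible"

    def test_redundant_drug_never_selected(self, toy):
        """Dropping any drug from the optimum must lose the blockage or
        worsen sigma: the -b sum(d) term strips redundant inhibitions."""
        model, catalog, objective = toy
        sol = ds.solve_optimal_combination(model, catalog, objective)
        for drug in sol.used_drugs:
            remaining = sol.used_drugs - {drug}
            still_blocks = (
                ds.max_flux(model, catalog, remaining, objective)
                < ds.MilpConfig().epsilon
            )
            if still_blocks:
                sigma = ds.side_effect(model, catalog, remaining, objective).sigma
                assert sigma > sol.sigma_oracle
            else:
                assert not still_blocks

    def test_min_drugs_forces_combination(self, toy_model):
        records = [
            ds.DrugRecord("direct", direct_target_reactions=frozenset({"v10"})),
            ds.DrugRecord("a", direct_target_reactions=frozenset({"v4"})),
            ds.DrugRecord("b", direct_target_reactions=frozenset({"v7"})),
        ]
        catalog = ds.build_catalog(records, toy_model, beta_bar=0.0)
        single = ds.solve_optimal_combination(toy_model, catalog, "v10")
        assert single.used_drugs == {"direct"}
        multi = ds.solve_optimal_combination(toy_model, catalog, "v10", min_drugs=2)
        assert len(multi.used_drugs) >= 2


class TestEnumerate:
    def test_toy_enumeration_order_and_termination(self, toy):
        model, catalog, objective = toy
        sols = ds.enumerate_solutions(model, catalog, objective)
        assert [sorted(s.used_drugs) for s in sols] == [
            ["drug_v4", "drug_v7"],
            ["drug_v2"],
        ]
        assert sols[0].sigma_oracle <= sols[1].sigma_oracle

    def test_max_solutions_truncates(self, toy):
        model, catalog, objective = toy
        assert len(ds.enumerate_solutions(model, catalog, objective, max_solutions=1)) == 1

    def test_unblockable_gives_empty_list(self, toy_model):
        records = [ds.DrugRecord("d9", direct_target_reactions=frozenset({"v9"}))]
        catalog = ds.build_catalog(records, toy_model, beta_bar=0.0)
        assert ds.enumerate_solutions(toy_model, catalog, "v1") == []

    def test_no_solution_is_superset_of_an_earlier_one(self, toy):
        model, catalog, objective = toy
        sols = ds.enumerate_solutions(model, catalog, objective)
        for i, a in enumerate(sols):
            for b in sols[i + 1:]:
                assert not a.used_drugs <= b.used_drugs


class TestVerify:
    def test_toy_solution_verifies_cleanly(self, toy, toy_solution):
        model, catalog, _ = toy
        report = ds.verify_solution(model, catalog, toy_solution)
        assert report.passed and report.sigma_match
        assert report.discrepancies == frozenset()

    def test_hand_built_solution_missing_drug_fails_inner_check(self, toy):
        model, catalog, objective = toy
        fake = ds.Solution(
            used_drugs=frozenset({"drug_v4"}),
            objective=objective,
            status="optimal",
            blocked_flags={r: False for r in model.reaction_ids},
        )
        report = ds.verify_solution(model, catalog, fake)
        assert not report.inner_ok

    def test_bottleneck_simultaneity_gap_detected(self, bottleneck):
        model, catalog, objective = bottleneck
        sol = ds.solve_optimal_combination(model, catalog, objective)
        assert sol.status == "optimal" and sol.used_drugs == {"drug_t"}
        report = ds.verify_solution(model, catalog, sol)
        assert report.inner_ok  # the drug really blocks the objective
        assert not report.passed  # but the internal count over-blocks a branch
        assert report.discrepancies  # one branch flagged stopped by the MILP
        assert report.discrepancies <= {"b1", "e1", "b2", "e2"}


@pytest.mark.parametrize("seed", range(1, 11))
def test_milp_matches_exhaustive_search(seed):
    """On random instances the MILP optimum's sigma equals the exhaustive
    subset-search optimum (drug identity may differ only under sigma ties)."""
    model, catalog, objective = ds.random_instance(ds.RandomInstanceSpec(seed=seed))
    sol = ds.solve_optimal_combination(model, catalog, objective)
    expected = BruteForceSearcher(model, catalog, objective).optimum()
    if sol.status == "optimal":
        assert expected is not None
        assert sol.sigma_oracle == pytest.approx(expected[1])
    else:
        assert expected is None
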