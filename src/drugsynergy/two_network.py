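"""Selective inhibition across two networks (e.g. cancer versus host).

One MILP couples two flux-balance models through the shared drug variables:
the *target* network carries the full primal/dual/strong-duality machinery
forcing its objective reaction to zero, while the *reference* network carries
only a primal flux block with activity indicators y. The outer objective
counts the side effect on the reference network alone,

    sum_j alpha_j (1 - y_j^ref) + sum_k beta_k (1 - d_k) - b sum_k d_k,

so the optimal drug set kills the target-cell objective while preserving as
much of the reference metabolism as possible (a soft preference, not a hard
constraint). The same compound exposes both cell types: a single d_k applies
to the drug's resolved targets in each model.

The additional-target screen asks, for each candidate reaction, whether
deleting it (from both networks, via the reaction correspondence) unlocks a
new or better drug solution — i.e. whether a hypothetical new inhibitor of
that reaction would synergize with the available drugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import blocking_oracle
from .drug_catalog import DrugCatalog
from .milp_synergy import (
    DegenerateInstanceError,
    MilpConfig,
    Solution,
    _Program,
    _resolve_columns,
    add_flux_block,
    add_indicator_block,
    add_objective_certificates,
)
from .network_model import MetabolicModel, parent_id

logger = logging.getLogger(__name__)


@dataclass
class NetworkPair:
    """A target model to inhibit and a reference model to preserve.

    ``correspondence`` maps target-model reaction ids to reference-model
    reaction ids (shared identifiers or EC-derived); ``catalog_target`` and
    ``catalog_reference`` resolve the same drugs against each model, carrying
    identical beta weights.
    """

    target_model: MetabolicModel
    reference_model: MetabolicModel
    catalog_target: DrugCatalog
    catalog_reference: DrugCatalog
    correspondence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, r in self.correspondence.items():
            self.target_model.columns_for(t)
            self.reference_model.columns_for(r)

    def drug_ids(self) -> list[str]:
        return sorted(
            set(self.catalog_target.targets) | set(self.catalog_reference.targets)
        )

    def reference_objective(self, objective: str) -> str | None:
        return self.correspondence.get(parent_id(objective))

    def with_deleted(self, reaction: str) -> tuple["NetworkPair", bool]:
        """Pair with a reaction zeroed in the target model and, when a
        correspondence exists, in the reference model too.

        Returns the new pair and whether the reference-side deletion applied.
        """
        target = self.target_model.with_zeroed({parent_id(reaction)})
        ref_id = self.correspondence.get(parent_id(reaction))
        if ref_id is not None:
            reference = self.reference_model.with_zeroed({parent_id(ref_id)})
            in_reference = True
        else:
            reference = self.reference_model
            in_reference = False
        pair = NetworkPair(
            target_model=target,
            reference_model=reference,
            catalog_target=self.catalog_target,
            catalog_reference=self.catalog_reference,
            correspondence=self.correspondence,
        )
        return pair, in_reference


def _build_selective(
    pair: NetworkPair,
    objective: str,
    config: MilpConfig,
    forbidden_cuts: Sequence[Iterable[str]] = (),
):
    prog = _Program()
    d_idx = {
        drug: prog.add_var(f"d_{drug}", 0.0, 1.0, integer=True)
        for drug in pair.drug_ids()
    }
    # target network: primal + duality, objective forced to zero
    t_cols = _resolve_columns(pair.target_model, pair.catalog_target)
    v_t, pairs_t = add_flux_block(prog, pair.target_model, d_idx, t_cols, tag="T")
    add_objective_certificates(
        prog,
        pair.target_model,
        v_t,
        d_idx,
        pairs_t,
        objective,
        config.delta_max,
        tag="T",
    )
    # reference network: primal + indicators only
    r_cols = _resolve_columns(pair.reference_model, pair.catalog_reference)
    v_r, _pairs_r = add_flux_block(prog, pair.reference_model, d_idx, r_cols, tag="R")
    y_r = add_indicator_block(prog, pair.reference_model, v_r, config.epsilon, tag="R")

    constant = 0.0
    for j, rid in enumerate(pair.reference_model.reaction_ids):
        a = config.alpha_of(rid)
        prog.obj[y_r[j]] = -a
        constant += a
    for drug in d_idx:
        beta = pair.catalog_reference.beta.get(
            drug, pair.catalog_target.beta.get(drug, 0.0)
        )
        prog.obj[d_idx[drug]] = -(beta + config.b)
        constant += beta
    for cut in forbidden_cuts:
        prog.add_row({d_idx[k]: 1.0 for k in cut}, lb=1.0, name="cut")
    return prog, d_idx, y_r, constant


def solve_selective(
    pair: NetworkPair,
    objective: str,
    config: MilpConfig | None = None,
    forbidden_cuts: Sequence[Iterable[str]] = (),
) -> Solution:
    """Block the objective in the target network, sparing the reference one.

    ``sigma_oracle`` is recomputed on the reference network; the reaction
    corresponding to the objective (when the correspondence defines one) is
    excluded from the count, so with reference = target the value matches the
    single-network solver.
    """
    config = config or MilpConfig()
    base_t = blocking_oracle.baseline_blocked(pair.target_model, config.epsilon)
    if parent_id(objective) in base_t:
        raise DegenerateInstanceError(
            f"objective {objective!r} carries no flux in the target network"
        )
    prog, d_idx, y_r, constant = _build_selective(
        pair, objective, config, forbidden_cuts
    )
    res = prog.solve(mip_gap=config.mip_gap, time_limit=config.time_limit)
    status = {0: "optimal", 1: "time_limit", 2: "infeasible", 3: "infeasible"}.get(
        res.status, "error"
    )
    if status != "optimal" or res.x is None:
        return Solution(used_drugs=frozenset(), objective=objective, status=status)
    x = res.x
    used = frozenset(k for k, idx in d_idx.items() if x[idx] < 0.5)
    blocked_flags = {
        rid: bool(x[y_r[j]] < 0.5)
        for j, rid in enumerate(pair.reference_model.reaction_ids)
    }
    sigma_milp = sum(
        config.alpha_of(rid) for rid, s in blocked_flags.items() if s
    ) + sum(pair.catalog_reference.beta.get(k, 0.0) for k in used)

    targets_t = frozenset().union(
        *(pair.catalog_target.targets.get(k, frozenset()) for k in used), frozenset()
    )
    inner_max = blocking_oracle.max_flux_targets(pair.target_model, targets_t, objective)
    raw_report = blocking_oracle.side_effect(
        pair.reference_model,
        pair.catalog_reference,
        used & set(pair.catalog_reference.targets),
        pair.reference_objective(objective),
        config.epsilon,
    )
    # beta accrues for every used drug, targeted in the reference model or not
    beta_term = float(
        sum(
            pair.catalog_reference.beta.get(k, pair.catalog_target.beta.get(k, 0.0))
            for k in used
        )
    )
    sigma_oracle = len(raw_report.stopped_reactions) + beta_term
    report = blocking_oracle.SideEffectReport(
        sigma=sigma_oracle,
        stopped_reactions=raw_report.stopped_reactions,
        beta_term=beta_term,
        drug_set=used,
    )
    return Solution(
        used_drugs=used,
        objective=objective,
        status=status,
        objective_value=float(res.fun + constant),
        sigma_milp=float(sigma_milp),
        sigma_oracle=float(sigma_oracle),
        inner_max=inner_max,
        blocked_flags=blocked_flags,
        oracle_report=report,
    )


def enumerate_selective(
    pair: NetworkPair,
    objective: str,
    config: MilpConfig | None = None,
    max_solutions: int | None = None,
) -> list[Solution]:
    """Hierarchical enumeration of selective solutions via exclusion cuts."""
    config = config or MilpConfig()
    out: list[Solution] = []
    cuts: list[frozenset[str]] = []
    while max_solutions is None or len(out) < max_solutions:
        if max_solutions == 0:
            break
        sol = solve_selective(pair, objective, config, forbidden_cuts=cuts)
        if sol.status != "optimal":
            break
        out.append(sol)
        if not sol.used_drugs:
            break
        cuts.append(sol.used_drugs)
    return out


@dataclass
class AdditionalTargetRow:
    """Outcome of deleting one candidate reaction before re-solving."""

    candidate: str
    solution: Solution | None
    flag: str  # deletion_lethal | new_inhibition | improved | unchanged | no_solution
    deleted_in_reference: bool
    baseline_sigma: float | None


def additional_target_screen(
    pair: NetworkPair,
    objective: str,
    config: MilpConfig | None = None,
    candidate_reactions: Iterable[str] | None = None,
) -> list[AdditionalTargetRow]:
    """Screen candidate reactions as hypothetical extra inhibition targets.

    Each candidate is deleted from the target network (and from the reference
    network through the correspondence; rows without a correspondence are
    flagged) and the selective problem is re-solved. Rows record whether a
    solution newly exists, improves on the no-deletion baseline, or whether
    the deletion alone already kills the objective.
    """
    config = config or MilpConfig()
    try:
        baseline = solve_selective(pair, objective, config)
        baseline_sigma = (
            baseline.sigma_oracle if baseline.status == "optimal" else None
        )
    except DegenerateInstanceError:
        raise  # a dead objective makes the whole screen meaningless
    if candidate_reactions is None:
        candidate_reactions = [
            p for p in pair.target_model.parents() if p != parent_id(objective)
        ]
    rows: list[AdditionalTargetRow] = []
    for cand in candidate_reactions:
        deleted, in_ref = pair.with_deleted(cand)
        try:
            sol = solve_selective(deleted, objective, config)
        except DegenerateInstanceError:
            rows.append(
                AdditionalTargetRow(cand, None, "deletion_lethal", in_ref, baseline_sigma)
            )
            continue
        if sol.status != "optimal":
            flag = "no_solution"
            sol_out = None
        elif baseline_sigma is None:
            flag = "new_inhibition"
            sol_out = sol
        elif sol.sigma_oracle < baseline_sigma:
            flag = "improved"
            sol_out = sol
        else:
            flag = "unchanged"
            sol_out = sol
        rows.append(
            AdditionalTargetRow(cand, sol_out, flag, in_ref, baseline_sigma)
        )
    return rows
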