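"""Synthetic instances: the worked toy network and seeded random instances.

Every stage of the pipeline is testable without any external reconstruction:

* :func:`toy_instance` builds the canonical 10-reaction illustration of drug
  synergism — three drugs sit at v2, v4 and v7 and the objective is v10;
  neither the drug at v4 nor the one at v7 stops v10 alone, the drug at v2
  stops every reaction in the network, and the pair {v4, v7} is the
  minimal-side-effect blocking set.
* :func:`random_instance` generates seeded branched-pathway networks
  (exchanges in, through a layered DAG, exchanges out) with random drug
  target sets — the workhorse of the MILP-vs-exhaustive-search equivalence
  suites.
* :func:`bottleneck_fixture` exposes the simultaneity gap: two branches share
  a capacity-limited upstream supply sized so each branch alone can carry the
  epsilon threshold but both together cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .drug_catalog import DrugCatalog, DrugRecord, build_catalog
from .network_model import MetabolicModel, RawModel, split_reversible
from . import blocking_oracle


def _raw_from_reactions(
    reactions: list[tuple[str, dict[str, float], float, float]],
    pathway: dict[str, str] | None = None,
    ec: dict[str, frozenset[str]] | None = None,
) -> RawModel:
    """Assemble a RawModel from (id, {metabolite: coef}, lower, upper) rows."""
    met_order: dict[str, int] = {}
    for _, stoich, _, _ in reactions:
        for met in stoich:
            met_order.setdefault(met, len(met_order))
    rows, cols, data = [], [], []
    for j, (_, stoich, _, _) in enumerate(reactions):
        for met, coef in stoich.items():
            rows.append(met_order[met]), cols.append(j), data.append(float(coef))
    S = sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(met_order), len(reactions))
    )
    return RawModel(
        metabolite_ids=list(met_order),
        reaction_ids=[r[0] for r in reactions],
        S=S,
        lower=np.array([r[2] for r in reactions], dtype=float),
        upper=np.array([r[3] for r in reactions], dtype=float),
        pathway=pathway or {},
        ec_numbers=ec or {},
    )


def toy_instance_raw() -> RawModel:
    """The toy network before canonicalization (all irreversible, U = 10)."""
    U = 10.0
    reactions = [
        ("v1", {"A": 1.0}, 0.0, U),                 # uptake -> A
        ("v2", {"A": -1.0, "B": 1.0}, 0.0, U),      # sole conduit A -> B
        ("v3", {"B": -1.0, "C": 1.0}, 0.0, U),
        ("v4", {"C": -1.0, "E": 1.0}, 0.0, U),      # drugged branch 1
        ("v5", {"B": -1.0, "D": 1.0}, 0.0, U),
        ("v6", {"C": -1.0}, 0.0, U),                # side export of C
        ("v7", {"D": -1.0, "E": 1.0}, 0.0, U),      # drugged branch 2
        ("v8", {"D": -1.0}, 0.0, U),                # side export of D
        ("v9", {"E": -1.0}, 0.0, U),                # export of E
        ("v10", {"E": -1.0}, 0.0, U),               # objective
    ]
    return _raw_from_reactions(reactions)


def toy_instance() -> tuple[MetabolicModel, DrugCatalog, str]:
    """The worked toy instance: model, three single-target drugs, objective v10.

    All beta weights are zero (the drugs have no non-metabolic targets), so
    sigma reduces to the newly-stopped-reaction count.
    """
    model = split_reversible(toy_instance_raw())
    records = [
        DrugRecord("drug_v2", name="drug at v2", direct_target_reactions=frozenset({"v2"})),
        DrugRecord("drug_v4", name="drug at v4", direct_target_reactions=frozenset({"v4"})),
        DrugRecord("drug_v7", name="drug at v7", direct_target_reactions=frozenset({"v7"})),
    ]
    catalog = build_catalog(records, model, beta_bar=0.0)
    return model, catalog, "v10"


def bottleneck_fixture() -> tuple[MetabolicModel, DrugCatalog, str]:
    """Two branches fed by a 0.15-capacity supply (epsilon = 0.1 semantics).

    Each branch alone sustains a 0.1 flux, but not both simultaneously, so
    the per-reaction LP oracle calls both branches unblocked while any single
    simultaneous flux pattern must leave one below threshold. A separate
    drugged linear path (u2 -> t) provides a trivial optimal solution whose
    verification exposes the gap.
    """
    reactions = [
        ("u1", {"A": 1.0}, 0.0, 0.15),
        ("b1", {"A": -1.0, "P1": 1.0}, 0.0, 10.0),
        ("e1", {"P1": -1.0}, 0.0, 10.0),
        ("b2", {"A": -1.0, "P2": 1.0}, 0.0, 10.0),
        ("e2", {"P2": -1.0}, 0.0, 10.0),
        ("u2", {"X": 1.0}, 0.0, 10.0),
        ("t", {"X": -1.0}, 0.0, 10.0),
    ]
    model = split_reversible(_raw_from_reactions(reactions))
    records = [
        DrugRecord("drug_t", direct_target_reactions=frozenset({"t"})),
    ]
    catalog = build_catalog(records, model, beta_bar=0.0)
    return model, catalog, "t"


@dataclass
class RandomInstanceSpec:
    """Parameters of a seeded random branched-pathway instance."""

    n_metabolites: int = 10
    n_internal_reactions: int = 14
    n_exchange: int = 3
    reversible_fraction: float = 0.2
    n_drugs: int = 6
    targets_per_drug: tuple[int, int] = (1, 3)
    nonmetabolic_count: tuple[int, int] = (0, 2)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_metabolites, self.n_internal_reactions) < 1:
            raise ValueError("counts must be positive")
        if self.n_drugs < 0 or self.n_exchange < 1:
            raise ValueError("invalid spec")


class GenerationError(RuntimeError):
    """The spec could not yield a flux-carrying objective reaction."""


def _random_raw(spec: RandomInstanceSpec, rng: np.random.Generator) -> RawModel:
    mets = [f"M{i}" for i in range(spec.n_metabolites)]
    reactions: list[tuple[str, dict[str, float], float, float]] = []
    # uptake exchanges feed the first metabolites
    n_in = max(1, spec.n_exchange // 2)
    for i in range(n_in):
        reactions.append((f"EX_in{i}", {mets[i % len(mets)]: 1.0}, 0.0, 1000.0))
    # internal reactions form a DAG over the metabolite ordering
    for r in range(spec.n_internal_reactions):
        hi = int(rng.integers(1, spec.n_metabolites))
        sub = int(rng.integers(0, hi))
        prod = int(rng.integers(sub + 1, spec.n_metabolites + 1))
        stoich = {mets[sub]: -1.0}
        if prod < spec.n_metabolites:
            stoich[mets[prod]] = 1.0
            if rng.random() < 0.25:  # occasional branched product
                extra = int(rng.integers(sub + 1, spec.n_metabolites))
                stoich.setdefault(mets[extra], 0.0)
                stoich[mets[extra]] += 1.0
        lower = -100.0 if rng.random() < spec.reversible_fraction else 0.0
        reactions.append((f"R{r}", stoich, lower, 100.0))
    # every produced metabolite can leave the system: consumers always exist
    produced = sorted(
        {m for _, st, _, _ in reactions for m, c in st.items() if c > 0}
    )
    for met in produced:
        reactions.append((f"EX_out{met}", {met: -1.0}, 0.0, 1000.0))
    return _raw_from_reactions(reactions)


def random_instance(
    spec: RandomInstanceSpec,
) -> tuple[MetabolicModel, DrugCatalog, str]:
    """Seeded random instance with a guaranteed flux-carrying objective.

    Networks are branched pathway DAGs from uptake to export exchanges, with
    capacities (100-1000) far above the 0.1 blocking threshold so that
    individually sustainable reactions are also jointly sustainable. Drugs
    get random internal-reaction target sets and small non-metabolic target
    counts; beta weights use the oracle-estimated beta_bar of the instance.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    for _attempt in range(100):
        raw = _random_raw(spec, rng)
        model = split_reversible(raw)
        base = blocking_oracle.baseline_blocked(model)
        internal = [
            r for r in model.parents() if r.startswith("R") and r not in base
        ]
        if not internal:
            continue
        objective = internal[int(rng.integers(0, len(internal)))]
        candidates = internal
        records = []
        for k in range(spec.n_drugs):
            lo, hi = spec.targets_per_drug
            n_t = int(rng.integers(lo, hi + 1))
            picked = rng.choice(len(candidates), size=min(n_t, len(candidates)), replace=False)
            nm_lo, nm_hi = spec.nonmetabolic_count
            records.append(
                DrugRecord(
                    f"D{k}",
                    direct_target_reactions=frozenset(candidates[i] for i in picked),
                    n_nonmetabolic_targets=int(rng.integers(nm_lo, nm_hi + 1)),
                )
            )
        catalog = build_catalog(records, model)
        return model, catalog, objective
    raise GenerationError(f"no flux-carrying objective after 100 attempts: {spec}")
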