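"""From a drug-annotation table to the optimization's drug set.

The pipeline mirrors a realistic curation of an approved-drug list: keep
approved drugs with an experimentally supported inhibitory metabolic target,
resolve EC numbers to model reactions (one EC may hit many reactions), merge
drugs with identical metabolic target sets into groups, and weight each drug's
non-metabolic targets.

The non-metabolic penalty of drug k is

    beta_k = beta_bar * (# non-metabolic targets of drug k),

where ``beta_bar`` is the mean number of metabolic reactions stopped when a
single metabolic target is inhibited, estimated with the LP blocking oracle
over all (drug, target) pairs of the catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from . import blocking_oracle
from .network_model import MetabolicModel, parent_id

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str = ""
    approved: bool = True
    inhibited_ec: frozenset[str] = frozenset()
    direct_target_reactions: frozenset[str] = frozenset()
    n_nonmetabolic_targets: int = 0


@dataclass
class DrugCatalog:
    """Grouped drugs with resolved targets and side-effect weights.

    ``targets`` maps each representative drug to the set of (collapsed)
    model reaction ids it inhibits; ``group_members`` lists the merged drug
    ids behind each representative.
    """

    drugs: list[DrugRecord] = field(default_factory=list)
    targets: dict[str, frozenset[str]] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)
    group_members: dict[str, list[str]] = field(default_factory=dict)
    beta_bar: float | None = None

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]

    def __len__(self) -> int:
        return len(self.drugs)


def filter_records(records: Iterable[DrugRecord]) -> list[DrugRecord]:
    """Keep approved drugs with at least one annotated metabolic target."""
    return [
        r
        for r in records
        if r.approved and (r.inhibited_ec or r.direct_target_reactions)
    ]


def map_targets(
    records: Iterable[DrugRecord], model: MetabolicModel
) -> dict[str, frozenset[str]]:
    """Resolve each drug's EC numbers and direct targets to model reactions.

    A drug maps to the union of all (collapsed) reactions whose EC annotation
    intersects the drug's inhibited set, plus any directly named target
    reactions. Drugs resolving to no model reaction are dropped with a
    warning.
    """
    ec_index: dict[str, set[str]] = {}
    for rid, ecs in model.ec_numbers.items():
        for ec in ecs:
            ec_index.setdefault(ec, set()).add(parent_id(rid))
    known = set(model.parents())
    out: dict[str, frozenset[str]] = {}
    for rec in records:
        targets: set[str] = set()
        for ec in rec.inhibited_ec:
            targets |= ec_index.get(ec, set())
        for rid in rec.direct_target_reactions:
            if parent_id(rid) in known:
                targets.add(parent_id(rid))
        if not targets:
            logger.warning(
                "drug %s: no target maps to a model reaction; dropped", rec.drug_id
            )
            continue
        out[rec.drug_id] = frozenset(targets)
    return out


def group_by_target_set(
    records: Iterable[DrugRecord], targets: dict[str, frozenset[str]]
) -> DrugCatalog:
    """Merge drugs with exactly the same metabolic target set.

    The group representative is the member with the minimal number of
    non-metabolic targets (ties by lexicographic drug id); only
    representatives enter the optimization.
    """
    by_set: dict[frozenset[str], list[DrugRecord]] = {}
    for rec in records:
        if rec.drug_id not in targets:
            continue
        by_set.setdefault(targets[rec.drug_id], []).append(rec)
    catalog = DrugCatalog()
    reps = []
    for tset, members in by_set.items():
        rep = min(members, key=lambda r: (r.n_nonmetabolic_targets, r.drug_id))
        reps.append((rep, tset, sorted(m.drug_id for m in members)))
    for rep, tset, member_ids in sorted(reps, key=lambda t: t[0].drug_id):
        catalog.drugs.append(rep)
        catalog.targets[rep.drug_id] = tset
        catalog.group_members[rep.drug_id] = member_ids
        catalog.beta[rep.drug_id] = 0.0
    return catalog


def estimate_beta_bar(
    model: MetabolicModel,
    catalog: DrugCatalog,
    epsilon: float = blocking_oracle.DEFAULT_EPSILON,
) -> float:
    """Mean number of reactions stopped per single inhibited metabolic target.

    For every (drug, target reaction) pair of the catalog, inhibit only that
    reaction and count the newly blocked reactions (including the target
    itself, excluding the baseline-blocked set); return the arithmetic mean
    over all pairs.
    """
    if not catalog.targets:
        raise ValueError("cannot estimate beta_bar from an empty catalog")
    base = blocking_oracle.baseline_blocked(model, epsilon)
    counts: list[int] = []
    cache: dict[str, int] = {}
    for drug in sorted(catalog.targets):
        for target in sorted(catalog.targets[drug]):
            if target not in cache:
                blocked = blocking_oracle.blocked_targets(
                    model, frozenset([target]), epsilon
                )
                cache[target] = len(blocked - base)
            counts.append(cache[target])
    return float(sum(counts)) / len(counts)


def compute_beta_weights(catalog: DrugCatalog, beta_bar: float) -> DrugCatalog:
    """Set beta_k = beta_bar * n_nonmetabolic_targets for each representative."""
    if beta_bar < 0:
        raise ValueError("beta_bar must be non-negative")
    catalog.beta_bar = beta_bar
    for rec in catalog.drugs:
        catalog.beta[rec.drug_id] = beta_bar * rec.n_nonmetabolic_targets
    return catalog


def build_catalog(
    records: Iterable[DrugRecord],
    model: MetabolicModel,
    epsilon: float = blocking_oracle.DEFAULT_EPSILON,
    beta_bar: float | None = None,
) -> DrugCatalog:
    """Full pipeline: filter, map, group, estimate beta_bar, weight."""
    kept = filter_records(records)
    targets = map_targets(kept, model)
    catalog = group_by_target_set(kept, targets)
    if catalog.targets:
        if beta_bar is None:
            beta_bar = estimate_beta_bar(model, catalog, epsilon)
        compute_beta_weights(catalog, beta_bar)
    return catalog


def load_drug_table(path) -> list[DrugRecord]:
    """Read a tab-separated drug table.

    Header columns: ``drug_id, name, approved, ec_list, direct_targets,
    n_nonmetabolic`` with semicolon-separated list fields.
    """
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"drug_id", "approved", "n_nonmetabolic"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        records.append(
            DrugRecord(
                drug_id=row["drug_id"],
                name=row.get("name", ""),
                approved=str(row["approved"]).strip().lower() in {"1", "true", "yes"},
                inhibited_ec=frozenset(
                    e for e in row.get("ec_list", "").split(";") if e
                ),
                direct_target_reactions=frozenset(
                    t for t in row.get("direct_targets", "").split(";") if t
                ),
                n_nonmetabolic_targets=int(row["n_nonmetabolic"] or 0),
            )
        )
    return records


def write_drug_table(records: Iterable[DrugRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tname\tapproved\tec_list\tdirect_targets\tn_nonmetabolic\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.drug_id,
                        r.name,
                        "true" if r.approved else "false",
                        ";".join(sorted(r.inhibited_ec)),
                        ";".join(sorted(r.direct_target_reactions)),
                        str(r.n_nonmetabolic_targets),
                    ]
                )
                + "\n"
            )
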