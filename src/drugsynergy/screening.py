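"""Network-wide screening and characterization of drug synergisms.

Every (collapsed) reaction of the network is tried in turn as the objective
to inhibit; the best multi-drug solution from the MILP is compared with the
pre-computed single-drug effects and classified:

* ``single_only``    — only a single drug stops the reaction;
* ``new_inhibition`` — no single drug can, but a combination does;
* ``more_selective`` — both exist and the combination has the smaller side
  effect;
* ``less_selective`` — both exist and the combination is worse;
* ``unblockable``    — nothing stops it.

Each multi-drug solution carries a synergy set Y (reactions stopped only by
the full combination); the summary `ratio` column reports 100*|Y|/sigma,
truncated to one decimal place. Profiles are compared by Jaccard (default)
or Hamming distance, clustered into a distance tree (average linkage, or
neighbor joining as used for phylogenies), and projected onto a drug
proximity graph linking drugs that share a synergistic interaction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import blocking_oracle
from .blocking_oracle import SynergyProfile
from .drug_catalog import DrugCatalog
from .milp_synergy import (
    DegenerateInstanceError,
    MilpConfig,
    Solution,
    solve_optimal_combination,
)
from .network_model import MetabolicModel

logger = logging.getLogger(__name__)

OUTCOMES = (
    "single_only",
    "new_inhibition",
    "more_selective",
    "less_selective",
    "unblockable",
)


@dataclass
class ScreenRow:
    """Outcome of screening one reaction as the objective to block."""

    objective: str
    pathway: str = ""
    outcome: str | None = None  # one of OUTCOMES; None if baseline-blocked
    baseline_blocked: bool = False
    best_single_drug: str | None = None
    best_single_sigma: float | None = None
    multi_solution: Solution | None = None
    profile: SynergyProfile | None = None
    ratio: float | None = None
    error: str | None = None


def single_drug_effects(
    model: MetabolicModel,
    catalog: DrugCatalog,
    epsilon: float = blocking_oracle.DEFAULT_EPSILON,
) -> dict[str, frozenset[str]]:
    """Blocked-reaction set of every single drug (cached for the screen)."""
    return {
        drug: blocking_oracle.blocked_reactions(model, catalog, [drug], epsilon)
        for drug in sorted(catalog.targets)
    }


def synergy_ratio(n_synergistic: int, sigma: float) -> float:
    """100 * |Y| / sigma, truncated (not rounded) to one decimal place.

    Undefined for sigma <= 0 (raises); |Y| = 0 gives 0.0.
    """
    if sigma <= 0:
        raise ValueError("ratio undefined for sigma <= 0")
    return math.floor(1000.0 * n_synergistic / sigma) / 10.0


def screen_all_objectives(
    model: MetabolicModel,
    catalog: DrugCatalog,
    config: MilpConfig | None = None,
    objectives: list[str] | None = None,
) -> list[ScreenRow]:
    """Screen every (collapsed) reaction as a potential objective.

    The multi-drug arm solves the MILP restricted to at least two used drugs;
    the single arm takes the minimal-sigma blocking drug from the cached
    single-drug effects. Per-row solver failures are recorded and the screen
    continues. Baseline-blocked reactions are excluded with a flag.
    """
    config = config or MilpConfig()
    base = blocking_oracle.baseline_blocked(model, config.epsilon)
    singles = single_drug_effects(model, catalog, config.epsilon)
    rows: list[ScreenRow] = []
    for objective in objectives if objectives is not None else model.parents():
        row = ScreenRow(objective=objective, pathway=model.pathway.get(objective, ""))
        if objective in base:
            row.baseline_blocked = True
            rows.append(row)
            continue
        # single arm, straight from the cached blocked sets
        best_single: tuple[float, str] | None = None
        for drug, blocked in singles.items():
            if objective not in blocked:
                continue
            sigma = len(blocked - base - {objective}) + catalog.beta.get(drug, 0.0)
            if best_single is None or (sigma, drug) < best_single:
                best_single = (sigma, drug)
        if best_single is not None:
            row.best_single_sigma, row.best_single_drug = best_single
        # multi arm: MILP with |used| >= 2
        try:
            sol = solve_optimal_combination(
                model, catalog, objective, config, min_drugs=2
            )
        except DegenerateInstanceError:  # pragma: no cover - filtered above
            row.baseline_blocked = True
            rows.append(row)
            continue
        except blocking_oracle.OracleError as exc:
            row.error = str(exc)
            rows.append(row)
            continue
        multi = sol if sol.status == "optimal" else None
        if multi is not None:
            row.multi_solution = multi
            row.profile = blocking_oracle.synergy_profile(
                model, catalog, multi.used_drugs, config.epsilon
            )
            if multi.sigma_oracle > 0:
                row.ratio = synergy_ratio(len(row.profile.Y), multi.sigma_oracle)
        # classification
        if multi is None and best_single is None:
            row.outcome = "unblockable"
        elif multi is None:
            row.outcome = "single_only"
        elif best_single is None:
            row.outcome = "new_inhibition"
        elif multi.sigma_oracle < row.best_single_sigma:
            row.outcome = "more_selective"
        else:
            row.outcome = "less_selective"
        rows.append(row)
    return rows


def screen_to_table(rows: list[ScreenRow]):
    """Flatten screen rows to a DataFrame mirroring the summary-table layout."""
    import pandas as pd

    records = []
    for r in rows:
        records.append(
            {
                "objective": r.objective,
                "pathway": r.pathway,
                "outcome": r.outcome or ("baseline_blocked" if r.baseline_blocked else "error"),
                "best_single_drug": r.best_single_drug or "",
                "best_single_sigma": r.best_single_sigma,
                "drugs": ";".join(sorted(r.multi_solution.used_drugs))
                if r.multi_solution
                else "",
                "side_effect": r.multi_solution.sigma_oracle if r.multi_solution else None,
                "synergism": len(r.profile.Y) if r.profile else None,
                "ratio": r.ratio,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Distances, trees, drug network
# ---------------------------------------------------------------------------

def _pair_distance(a: frozenset, b: frozenset, metric: str, n_universe: int) -> float:
    if metric == "jaccard":
        if not a and not b:
            return 0.0
        union = len(a | b)
        return 1.0 - len(a & b) / union
    if metric == "hamming":
        return len(a ^ b) / float(n_universe)
    raise ValueError(f"unknown metric {metric!r}")


def distance_matrix(
    profiles: list[SynergyProfile], metric: str = "jaccard"
) -> np.ndarray:
    """Symmetric pairwise distance matrix between synergy sets Y.

    Jaccard: 1 - |Y1 & Y2| / |Y1 | Y2| (two empty sets are at distance 0);
    Hamming: fraction of the reaction universe where the s vectors differ.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    universe = profiles[0].universe
    for p in profiles:
        if p.universe != universe:
            raise ValueError("profiles must share one reaction universe")
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _pair_distance(
                profiles[i].Y, profiles[j].Y, metric, len(universe)
            )
    return D


def profile_label(profile: SynergyProfile) -> str:
    return "+".join(sorted(profile.combination))


def cluster_tree(
    matrix: np.ndarray,
    labels: list[str],
    method: str = "average",
) -> str:
    """Hierarchical distance tree over the profiles, as a Newick string.

    ``average`` runs UPGMA-style average linkage; ``nj`` runs neighbor
    joining (the method used for phylogenetic trees) via scikit-bio.
    """
    n = matrix.shape[0]
    if n < 2 or len(labels) != n:
        raise ValueError("need a square matrix over >= 2 labeled profiles")
    if method == "nj":
        from skbio import DistanceMatrix
        from skbio.tree import nj

        tree = nj(DistanceMatrix(matrix, ids=labels))
        return str(tree).strip()
    if method != "average":
        raise ValueError(f"unknown method {method!r}")
    Z = hierarchy.linkage(squareform(matrix, checks=False), method="average")
    return _linkage_to_newick(Z, labels)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        la = f"{node(int(a))}:{h / 2 - heights[int(a)]:.6g}"
        lb = f"{node(int(b))}:{h / 2 - heights[int(b)]:.6g}"
        heights[i] = h / 2
        return f"({la},{lb})"

    for i in range(len(Z)):
        heights[n + i] = Z[i][2] / 2
    return node(n + len(Z) - 1) + ";"


def flat_clusters(
    matrix: np.ndarray, labels: list[str], threshold: float
) -> dict[str, int]:
    """Cut the average-linkage tree at a distance threshold into classes."""
    Z = hierarchy.linkage(squareform(matrix, checks=False), method="average")
    assignment = hierarchy.fcluster(Z, t=threshold, criterion="distance")
    return {lab: int(c) for lab, c in zip(labels, assignment)}


def drug_proximity_network(
    profiles: list[SynergyProfile], catalog: DrugCatalog | None = None
) -> nx.Graph:
    """Graph of drugs linked whenever they share a synergistic interaction.

    A combination of m drugs contributes an m-clique; edge weights accumulate
    |Y| over the interactions sharing the edge. Node attribute ``n_targets``
    (drawn as circle size) is the drug's number of direct targets.
    """
    G = nx.Graph()
    for prof in profiles:
        drugs = sorted(prof.combination)
        for d in drugs:
            if not G.has_node(d):
                n_targets = len(catalog.targets.get(d, ())) if catalog else 0
                G.add_node(d, n_targets=n_targets)
        for i in range(len(drugs)):
            for j in range(i + 1, len(drugs)):
                a, b = drugs[i], drugs[j]
                w = len(prof.Y)
                if G.has_edge(a, b):
                    G[a][b]["weight"] += w
                    G[a][b]["n_synergisms"] += 1
                else:
                    G.add_edge(a, b, weight=w, n_synergisms=1)
    return G
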