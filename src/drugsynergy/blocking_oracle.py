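"""LP ground truth for inhibition effects.

Everything reported about a drug combination — which reactions it stops, its
side-effect score sigma(D), the synergy set Y — is defined here by direct
linear programming on the flux space, independently of the MILP. The MILP
module treats these functions as the verification oracle.

A drug inhibits its target reactions completely: each targeted flux is forced
to zero. A (collapsed) reaction counts as *blocked* when no direction of it
can carry a flux of at least ``epsilon`` in any steady state of the inhibited
network. The side effect of a drug set D is

    sigma(D) = |newly blocked reactions| + sum_{k in D} beta_k

with the objective reaction and reactions already blocked in the unperturbed
network excluded from the count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np
from scipy.optimize import linprog

from .network_model import MetabolicModel, parent_id

if TYPE_CHECKING:  # pragma: no cover
    from .drug_catalog import DrugCatalog

logger = logging.getLogger(__name__)

#: Default flux threshold below which a reaction counts as stopped.
DEFAULT_EPSILON = 0.1

#: LP feasibility tolerance subtracted before the strict < epsilon comparison.
LP_TOL = 1e-6


class OracleError(RuntimeError):
    """Raised when the underlying LP solver fails unexpectedly."""


@dataclass
class SideEffectReport:
    """Side effect of a drug set, per the oracle semantics."""

    sigma: float
    stopped_reactions: frozenset[str]
    beta_term: float
    drug_set: frozenset[str]


@dataclass
class SynergyProfile:
    """Synergy fingerprint of a drug combination.

    ``Y`` holds the reactions stopped by the full combination but by none of
    its single drugs; ``s`` is the corresponding 0/1 vector over the collapsed
    reaction universe.
    """

    combination: frozenset[str]
    Y: frozenset[str]
    universe: tuple[str, ...]

    @property
    def s(self) -> np.ndarray:
        return np.array([1 if r in self.Y else 0 for r in self.universe], dtype=int)


def _targets_of(catalog: "DrugCatalog", drug_set: Iterable[str]) -> frozenset[str]:
    out: set[str] = set()
    for k in drug_set:
        if k not in catalog.targets:
            raise KeyError(f"unknown drug id {k!r}")
        out |= set(catalog.targets[k])
    return frozenset(out)


def _max_flux_cols(
    model: MetabolicModel,
    maximize_cols: list[int],
    forced_off: frozenset[str],
    zero_cols: Iterable[int] = (),
) -> tuple[float, np.ndarray]:
    """LP max of a sum of flux components over H with targets forced to zero."""
    upper = model.upper.copy()
    for p in forced_off:
        for j in model.columns_for(p):
            upper[j] = 0.0
    for j in zero_cols:
        upper[j] = 0.0
    c = np.zeros(model.n_reactions)
    c[maximize_cols] = -1.0
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([np.zeros_like(upper), upper]),
        method="highs",
    )
    if not res.success:
        raise OracleError(f"LP failed: {res.message}")
    return -res.fun, res.x


def max_flux_targets(
    model: MetabolicModel, forced_off: frozenset[str], reaction: str
) -> float:
    """Largest *net* flux the reaction can carry, maximizing each direction.

    For a split reversible reaction the opposite direction is held at zero
    while one direction is maximized (the raw reaction's flux is the net of
    the pair; the forward/reverse futile cycle is a canonicalization artifact
    and never counts as activity), and the value is the max over the two
    directions — a collapsed reaction is blocked only when both are.
    """
    best = 0.0
    cols = model.columns_for(reaction)
    for j in cols:
        others = [c for c in cols if c != j]
        val, _ = _max_flux_cols(model, [j], forced_off, zero_cols=others)
        best = max(best, val)
    return best


def max_flux(
    model: MetabolicModel,
    catalog: "DrugCatalog",
    drug_set: Iterable[str],
    reaction: str,
) -> float:
    """LP maximum of a reaction's flux under a drug set (targets zeroed)."""
    return max_flux_targets(model, _targets_of(catalog, drug_set), reaction)


def blocked_targets(
    model: MetabolicModel, forced_off: frozenset[str], epsilon: float = DEFAULT_EPSILON
) -> frozenset[str]:
    """Collapsed reactions unable to reach epsilon flux when targets are off.

    Uses witness reuse: every LP optimum is scanned and any reaction seen
    carrying >= epsilon flux is marked active without its own LP.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    thresh = epsilon - LP_TOL

    def mark_active(v: np.ndarray, active: set[str]) -> None:
        # net flux per parent: cancel any forward/reverse futile component
        for p, cols in parent_cols.items():
            if len(cols) == 1:
                if v[cols[0]] >= thresh:
                    active.add(p)
            elif abs(v[cols[0]] - v[cols[1]]) >= thresh:
                active.add(p)

    parent_cols = {p: model.columns_for(p) for p in model.parents()}
    active: set[str] = set()
    blocked: set[str] = set()
    for p, cols in parent_cols.items():
        if p in active:
            continue
        is_blocked = True
        for j in cols:
            others = [c for c in cols if c != j]
            val, v = _max_flux_cols(model, [j], forced_off, zero_cols=others)
            mark_active(v, active)
            if val >= thresh:
                is_blocked = False
                break
        if is_blocked and p not in active:
            blocked.add(p)
    return frozenset(blocked)


def blocked_reactions(
    model: MetabolicModel,
    catalog: "DrugCatalog",
    drug_set: Iterable[str],
    epsilon: float = DEFAULT_EPSILON,
) -> frozenset[str]:
    """Collapsed reactions blocked by a drug set (strict < epsilon maxima)."""
    return blocked_targets(model, _targets_of(catalog, drug_set), epsilon)


def baseline_blocked(
    model: MetabolicModel, epsilon: float = DEFAULT_EPSILON
) -> frozenset[str]:
    """Reactions blocked with no drugs at all (excluded from all counts)."""
    return blocked_targets(model, frozenset(), epsilon)


def side_effect(
    model: MetabolicModel,
    catalog: "DrugCatalog",
    drug_set: Iterable[str],
    objective: str | None,
    epsilon: float = DEFAULT_EPSILON,
    _baseline: frozenset[str] | None = None,
) -> SideEffectReport:
    """Side-effect score sigma(D) of a drug set.

    The stopped-reaction count excludes the objective reaction (always stopped
    by construction in a successful treatment) and the baseline-blocked set;
    the beta term adds each used drug's non-metabolic penalty.
    """
    drug_set = frozenset(drug_set)
    base = baseline_blocked(model, epsilon) if _baseline is None else _baseline
    blocked = blocked_reactions(model, catalog, drug_set, epsilon)
    stopped = blocked - base
    if objective is not None:
        stopped -= {parent_id(objective)}
    beta_term = float(sum(catalog.beta.get(k, 0.0) for k in drug_set))
    return SideEffectReport(
        sigma=len(stopped) + beta_term,
        stopped_reactions=frozenset(stopped),
        beta_term=beta_term,
        drug_set=drug_set,
    )


def synergy_profile(
    model: MetabolicModel,
    catalog: "DrugCatalog",
    combination: Iterable[str],
    epsilon: float = DEFAULT_EPSILON,
) -> SynergyProfile:
    """Reactions stopped only by the full combination, not by any single drug."""
    combination = frozenset(combination)
    if len(combination) < 2:
        raise ValueError("a synergy profile needs at least two drugs")
    together = blocked_reactions(model, catalog, combination, epsilon)
    singles: set[str] = set()
    for k in sorted(combination):
        singles |= blocked_reactions(model, catalog, [k], epsilon)
    Y = together - singles
    return SynergyProfile(
        combination=combination, Y=frozenset(Y), universe=tuple(model.parents())
    )


# ---------------------------------------------------------------------------
# Exhaustive search (test oracle; exponential, small catalogs only)
# ---------------------------------------------------------------------------

@dataclass
class BruteForceSearcher:
    """Memoized exhaustive search over drug subsets.

    Feasibility (does the subset block the objective?) and sigma are cached by
    the *union of forced-off target reactions*, so distinct subsets with the
    same metabolic footprint share one LP batch. Supports the same exclusion
    cuts as the MILP enumeration: a forbidden set rules out itself and all of
    its supersets.
    """

    model: MetabolicModel
    catalog: "DrugCatalog"
    objective: str
    epsilon: float = DEFAULT_EPSILON
    _feas: dict[frozenset[str], bool] = field(default_factory=dict)
    _sigma: dict[frozenset[str], SideEffectReport] = field(default_factory=dict)
    _base: frozenset[str] | None = None

    def _baseline(self) -> frozenset[str]:
        if self._base is None:
            self._base = baseline_blocked(self.model, self.epsilon)
        return self._base

    def blocks_objective(self, drug_set: frozenset[str]) -> bool:
        key = _targets_of(self.catalog, drug_set)
        if key not in self._feas:
            self._feas[key] = (
                max_flux_targets(self.model, key, self.objective)
                < self.epsilon - LP_TOL
            )
        return self._feas[key]

    def sigma(self, drug_set: frozenset[str]) -> float:
        key = _targets_of(self.catalog, drug_set)
        if key not in self._sigma:
            self._sigma[key] = side_effect(
                self.model,
                self.catalog,
                drug_set,
                self.objective,
                self.epsilon,
                _baseline=self._baseline(),
            )
        rep = self._sigma[key]
        # the count part depends only on the target union; the beta term does not
        beta_term = float(sum(self.catalog.beta.get(k, 0.0) for k in drug_set))
        return len(rep.stopped_reactions) + beta_term

    def optimum(
        self,
        max_cardinality: int | None = None,
        forbidden_cuts: list[frozenset[str]] = (),
    ) -> tuple[frozenset[str], float] | None:
        """Minimal-sigma blocking subset, or None if the objective is unblockable.

        Ties are broken by fewer drugs, then lexicographic drug ids. Subsets
        containing any forbidden set entirely are skipped.
        """
        drugs = sorted(self.catalog.targets)
        n = len(drugs)
        limit = n if max_cardinality is None else min(n, max_cardinality)
        best: tuple[float, int, tuple[str, ...]] | None = None
        cuts = [frozenset(c) for c in forbidden_cuts]
        for size in range(0, limit + 1):
            for combo in itertools.combinations(drugs, size):
                sub = frozenset(combo)
                if any(cut <= sub for cut in cuts):
                    continue
                if not self.blocks_objective(sub):
                    continue
                key = (self.sigma(sub), len(sub), tuple(sorted(sub)))
                if best is None or key < best:
                    best = key
        if best is None:
            return None
        return frozenset(best[2]), best[0]


def brute_force_optimum(
    model: MetabolicModel,
    catalog: "DrugCatalog",
    objective: str,
    epsilon: float = DEFAULT_EPSILON,
    max_cardinality: int | None = None,
):
    """Exhaustive minimal-sigma blocking drug set (None if infeasible)."""
    searcher = BruteForceSearcher(model, catalog, objective, epsilon)
    return searcher.optimum(max_cardinality=max_cardinality)
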