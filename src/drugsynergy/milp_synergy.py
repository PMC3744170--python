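"""Optimal drug combinations by a duality-reformulated single-level MILP.

The underlying problem is bilevel: the outer level picks the drug set D
(binary d_k, with d_k = 0 meaning drug k is used) minimizing the side effect

    sum_j alpha_j (1 - y_j) + sum_k beta_k (1 - d_k) - b sum_k d_k,

subject to the inner level — maximize the objective reaction's flux over the
inhibited flux space H(D) — attaining zero. The inner LP is replaced by its
dual feasibility conditions plus the strong-duality equality

    v_obj = sum_j U_j lambda_j + sum_(j,k) U_j z_jk,    z_jk := delta_jk d_k,

where mu (metabolites, free), lambda >= 0 (capacities) and delta >= 0 (one per
(target reaction, drug) coupling constraint) are the inner duals. The bilinear
products delta*d are linearized exactly with the big-M pairs

    0 <= z_jk <= delta_max d_k,
    delta_jk - delta_max (1 - d_k) <= z_jk <= delta_jk.

Binary y_j indicates whether reaction j carries at least epsilon flux
(eps y_j <= v_j <= U_j y_j); reverse-direction pairs add y_j + y_l <= 1 so a
reversible reaction is never counted active twice. The -b sum d_k term
(b << 1) strips redundant drugs from optimal sets.

Suboptimal solutions are enumerated hierarchically: after each optimum D* the
exclusion cut sum_{k in D*} d_k >= 1 is appended (forbidding D* and all its
supersets) and the MILP is re-solved until it becomes infeasible.

All reported sigma values are re-computed with the independent LP oracle in
:mod:`blocking_oracle`; the MILP's internal y-count can differ on networks
where reactions are individually but not simultaneously sustainable at
epsilon (the "simultaneity gap"), which :func:`verify_solution` detects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import blocking_oracle
from .blocking_oracle import SideEffectReport
from .drug_catalog import DrugCatalog
from .network_model import MetabolicModel, parent_id

logger = logging.getLogger(__name__)


class DegenerateInstanceError(RuntimeError):
    """The objective is already blocked with no drugs: report the empty set."""


@dataclass
class MilpConfig:
    """Tunable parameters of the MILP.

    epsilon : flux threshold below which a reaction counts as stopped (must be
        smaller than the smallest positive capacity).
    b : small bonus per unused drug; excludes redundant inhibitions.
    delta_max : big-M upper bound for the dual variables delta.
    alpha : optional per-reaction weight in the stopped-reaction term
        (default 1 for every reaction).
    mip_gap : relative MIP optimality gap passed to the solver.
    time_limit : wall-clock limit in seconds (None = no limit).
    """

    epsilon: float = 0.1
    b: float = 0.001
    delta_max: float = 1000.0
    alpha: dict[str, float] | None = None
    mip_gap: float = 0.0
    time_limit: float | None = None

    def alpha_of(self, reaction_id: str) -> float:
        if self.alpha is None:
            return 1.0
        return self.alpha.get(reaction_id, 1.0)


# ---------------------------------------------------------------------------
# Generic sparse MILP assembler (thin layer over scipy.optimize.milp / HiGHS)
# ---------------------------------------------------------------------------

class _Program:
    def __init__(self) -> None:
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integer: list[bool] = []
        self.obj: list[float] = []
        self.names: list[str] = []
        self._rows_i: list[int] = []
        self._cols_j: list[int] = []
        self._data: list[float] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []
        self._row_names: list[str] = []

    @property
    def n_vars(self) -> int:
        return len(self.lb)

    @property
    def n_rows(self) -> int:
        return len(self._row_lb)

    def add_var(self, name, lb=0.0, ub=np.inf, integer=False, obj=0.0) -> int:
        self.names.append(name)
        self.lb.append(lb)
        self.ub.append(ub)
        self.integer.append(integer)
        self.obj.append(obj)
        return self.n_vars - 1

    def add_row(self, coeffs: dict[int, float], lb=-np.inf, ub=np.inf, name="") -> int:
        r = self.n_rows
        for j, c in coeffs.items():
            if c != 0.0:
                self._rows_i.append(r)
                self._cols_j.append(j)
                self._data.append(float(c))
        self._row_lb.append(lb)
        self._row_ub.append(ub)
        self._row_names.append(name or f"c{r}")
        return r

    def solve(self, mip_gap: float = 0.0, time_limit: float | None = None):
        A = sparse.csr_matrix(
            (self._data, (self._rows_i, self._cols_j)),
            shape=(self.n_rows, self.n_vars),
        )
        options: dict = {"mip_rel_gap": mip_gap}
        if time_limit is not None:
            options["time_limit"] = time_limit
        res = milp(
            c=np.asarray(self.obj),
            constraints=LinearConstraint(A, np.asarray(self._row_lb), np.asarray(self._row_ub)),
            integrality=np.asarray(self.integer, dtype=int),
            bounds=Bounds(np.asarray(self.lb), np.asarray(self.ub)),
            options=options,
        )
        return res

    def to_lp_string(self) -> str:
        """Minimal CPLEX-LP-style dump of the instance, for debugging."""
        by_row: dict[int, list[tuple[int, float]]] = {}
        for r, j, c in zip(self._rows_i, self._cols_j, self._data):
            by_row.setdefault(r, []).append((j, c))
        out = ["Minimize", " obj: " + _lin_str(enumerate(self.obj), self.names)]
        out.append("Subject To")
        for r in range(self.n_rows):
            expr = _lin_str(by_row.get(r, []), self.names)
            lo, hi = self._row_lb[r], self._row_ub[r]
            if lo == hi:
                out.append(f" {self._row_names[r]}: {expr} = {lo:g}")
            else:
                if np.isfinite(hi):
                    out.append(f" {self._row_names[r]}: {expr} <= {hi:g}")
                if np.isfinite(lo):
                    out.append(f" {self._row_names[r]}_lo: {expr} >= {lo:g}")
        out.append("Bounds")
        for j, (lo, hi) in enumerate(zip(self.lb, self.ub)):
            out.append(f" {lo:g} <= {self.names[j]} <= {hi:g}")
        binaries = [self.names[j] for j in range(self.n_vars) if self.integer[j]]
        if binaries:
            out.append("Binary")
            out.append(" " + " ".join(binaries))
        out.append("End")
        return "\n".join(out)


def _lin_str(terms, names) -> str:
    parts = []
    for j, c in terms:
        if c == 0.0:
            continue
        sign = "-" if c < 0 else ("+" if parts else "")
        parts.append(f"{sign} {abs(c):g} {names[j]}".strip())
    return " ".join(parts) if parts else "0"


# ---------------------------------------------------------------------------
# Building blocks shared with the two-network variant
# ---------------------------------------------------------------------------

def _resolve_columns(model: MetabolicModel, catalog: DrugCatalog):
    """Per-drug list of split-column indices targeted in this model."""
    out: dict[str, list[int]] = {}
    for drug, parents in catalog.targets.items():
        cols: list[int] = []
        for p in sorted(parents):
            cols.extend(model.columns_for(p))
        out[drug] = cols
    return out


def add_flux_block(prog, model, d_idx, drug_cols, tag=""):
    """Primal block: v variables, steady state, drug-target coupling.

    Returns (v indices, list of (column, drug, pair-row) target couplings).
    """
    v = [
        prog.add_var(f"v{tag}_{rid}", 0.0, float(model.upper[j]))
        for j, rid in enumerate(model.reaction_ids)
    ]
    Scsr = model.S.tocsr()
    for i in range(model.n_metabolites):
        row = Scsr.getrow(i)
        prog.add_row(
            {v[j]: c for j, c in zip(row.indices, row.data)},
            lb=0.0,
            ub=0.0,
            name=f"mass{tag}_{model.metabolite_ids[i]}",
        )
    pairs: list[tuple[int, str]] = []
    for drug in sorted(drug_cols):
        for j in drug_cols[drug]:
            prog.add_row(
                {v[j]: 1.0, d_idx[drug]: -float(model.upper[j])},
                ub=0.0,
                name=f"tgt{tag}_{model.reaction_ids[j]}_{drug}",
            )
            pairs.append((j, drug))
    return v, pairs


def add_indicator_block(prog, model, v, epsilon, tag=""):
    """y indicators (eps y <= v <= U y) plus reverse-pair exclusion rows."""
    y = [
        prog.add_var(f"y{tag}_{rid}", 0.0, 1.0, integer=True)
        for rid in model.reaction_ids
    ]
    for j, rid in enumerate(model.reaction_ids):
        prog.add_row({y[j]: epsilon, v[j]: -1.0}, ub=0.0, name=f"ylo{tag}_{rid}")
        prog.add_row(
            {v[j]: 1.0, y[j]: -float(model.upper[j])}, ub=0.0, name=f"yhi{tag}_{rid}"
        )
    for rid, twin in model.reverse_pair.items():
        if rid < twin:
            prog.add_row(
                {y[model.index(rid)]: 1.0, y[model.index(twin)]: 1.0},
                ub=1.0,
                name=f"pair{tag}_{rid}",
            )
    return y


def add_duality_block(
    prog, model, v, d_idx, pairs, objective_cols, delta_max, tag="", lam_upper=None
):
    """Inner-LP dual feasibility, strong-duality equality and linearization.

    Appends the dual certificate that the inner maximum of the objective flux
    is zero. ``lam_upper`` overrides the capacity vector weighting the lambda
    duals in the strong-duality equality (used to hold the reverse twin of a
    reversible objective at zero in its direction's certificate).
    """
    if lam_upper is None:
        lam_upper = model.upper
    mu = [
        prog.add_var(f"mu{tag}_{mid}", -np.inf, np.inf) for mid in model.metabolite_ids
    ]
    lam = [
        prog.add_var(f"lam{tag}_{rid}", 0.0, np.inf) for rid in model.reaction_ids
    ]
    delta = {}
    z = {}
    for j, drug in pairs:
        delta[(j, drug)] = prog.add_var(
            f"delta{tag}_{model.reaction_ids[j]}_{drug}", 0.0, delta_max
        )
        z[(j, drug)] = prog.add_var(
            f"z{tag}_{model.reaction_ids[j]}_{drug}", 0.0, delta_max
        )

    # dual feasibility: S^T mu + lambda + sum_k delta_jk >= c_j
    Scsc = model.S.tocsc()
    deltas_of: dict[int, list[int]] = {}
    for (j, drug), idx in delta.items():
        deltas_of.setdefault(j, []).append(idx)
    for j, rid in enumerate(model.reaction_ids):
        col = Scsc.getcol(j)
        coeffs = {mu[i]: c for i, c in zip(col.indices, col.data)}
        coeffs[lam[j]] = 1.0
        for idx in deltas_of.get(j, []):
            coeffs[idx] = 1.0
        rhs = 1.0 if j in objective_cols else 0.0
        prog.add_row(coeffs, lb=rhs, name=f"dual{tag}_{rid}")

    # strong duality: v_obj (= 0) = sum_j U'_j lam_j + sum_(j,k) U_j z_jk
    coeffs = {lam[j]: float(lam_upper[j]) for j in range(model.n_reactions)}
    for (j, drug), idx in z.items():
        coeffs[idx] = coeffs.get(idx, 0.0) + float(model.upper[j])
    prog.add_row(coeffs, lb=0.0, ub=0.0, name=f"strongdual{tag}")

    # exact linearization of z = delta * d
    for (j, drug), zidx in z.items():
        didx = delta[(j, drug)]
        dk = d_idx[drug]
        prog.add_row({zidx: 1.0, dk: -delta_max}, ub=0.0, name=f"zub{tag}_{j}_{drug}")
        prog.add_row({zidx: 1.0, didx: -1.0}, ub=0.0, name=f"zled{tag}_{j}_{drug}")
        prog.add_row(
            {didx: 1.0, zidx: -1.0, dk: delta_max},
            ub=delta_max,
            name=f"zlb{tag}_{j}_{drug}",
        )
    return mu, lam, delta, z


def add_objective_certificates(
    prog, model, v, d_idx, pairs, objective, delta_max, tag=""
):
    """Force v_obj = 0 and certify that its inner maximum is zero.

    An irreversible objective gets the single certificate of the standard
    formulation. A reversible objective must be unable to carry *net* flux
    in either direction (the split pair's futile cycle is a canonicalization
    artifact, not activity), so each direction gets its own certificate in
    which the opposite twin's capacity is held at zero.
    """
    cols = model.columns_for(objective)
    for j in cols:
        prog.ub[v[j]] = 0.0
    blocks = []
    if len(cols) == 1:
        blocks.append(
            add_duality_block(prog, model, v, d_idx, pairs, cols, delta_max, tag=tag)
        )
    else:
        for i, c in enumerate(cols):
            lam_upper = model.upper.copy()
            for other in cols:
                if other != c:
                    lam_upper[other] = 0.0
            blocks.append(
                add_duality_block(
                    prog, model, v, d_idx, pairs, [c], delta_max,
                    tag=f"{tag}dir{i}", lam_upper=lam_upper,
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# Instance assembly
# ---------------------------------------------------------------------------

@dataclass
class MilpInstance:
    """Assembled single-level MILP plus the index maps to read a solution."""

    prog: _Program
    model: MetabolicModel
    catalog: DrugCatalog
    objective: str
    config: MilpConfig
    v: list[int]
    y: list[int]
    d: dict[str, int]
    certificates: list[tuple]  # one (mu, lam, delta, z) block per net direction
    objective_constant: float

    @property
    def delta(self) -> dict:
        if len(self.certificates) == 1:
            return self.certificates[0][2]
        return {
            (i, *key): idx
            for i, block in enumerate(self.certificates)
            for key, idx in block[2].items()
        }

    @property
    def z(self) -> dict:
        if len(self.certificates) == 1:
            return self.certificates[0][3]
        return {
            (i, *key): idx
            for i, block in enumerate(self.certificates)
            for key, idx in block[3].items()
        }

    @property
    def n_binaries(self) -> int:
        return len(self.y) + len(self.d)

    @property
    def n_z(self) -> int:
        return len(self.z)

    def to_lp_string(self) -> str:
        return self.prog.to_lp_string()


def build_milp(
    model: MetabolicModel,
    catalog: DrugCatalog,
    objective: str,
    config: MilpConfig | None = None,
    forbidden_cuts: Sequence[Iterable[str]] = (),
    min_drugs: int = 0,
) -> MilpInstance:
    """Assemble the duality-reformulated MILP for one network.

    ``forbidden_cuts`` adds one exclusion row per previously found drug set;
    ``min_drugs`` restricts to solutions using at least that many drugs (used
    by the screen to force genuine combinations).

    Raises :class:`DegenerateInstanceError` if the objective is blocked with
    no drugs at all — the caller should report the empty solution.
    """
    config = config or MilpConfig()
    base = blocking_oracle.baseline_blocked(model, config.epsilon)
    if parent_id(objective) in base:
        raise DegenerateInstanceError(
            f"objective {objective!r} carries no flux even without drugs"
        )

    prog = _Program()
    d_idx = {
        drug: prog.add_var(f"d_{drug}", 0.0, 1.0, integer=True)
        for drug in sorted(catalog.targets)
    }
    drug_cols = _resolve_columns(model, catalog)
    v, pairs = add_flux_block(prog, model, d_idx, drug_cols)
    certificates = add_objective_certificates(
        prog, model, v, d_idx, pairs, objective, config.delta_max
    )
    y = add_indicator_block(prog, model, v, config.epsilon)

    # outer objective: sum alpha (1-y) + sum beta (1-d) - b sum d
    constant = 0.0
    for j, rid in enumerate(model.reaction_ids):
        a = config.alpha_of(rid)
        prog.obj[y[j]] = -a
        constant += a
    for drug in d_idx:
        beta = catalog.beta.get(drug, 0.0)
        prog.obj[d_idx[drug]] = -(beta + config.b)
        constant += beta

    for cut in forbidden_cuts:
        prog.add_row({d_idx[k]: 1.0 for k in cut}, lb=1.0, name="cut")
    if min_drugs > 0:
        prog.add_row(
            {idx: 1.0 for idx in d_idx.values()},
            ub=len(d_idx) - min_drugs,
            name="min_drugs",
        )

    return MilpInstance(
        prog=prog,
        model=model,
        catalog=catalog,
        objective=objective,
        config=config,
        v=v,
        y=y,
        d=d_idx,
        certificates=certificates,
        objective_constant=constant,
    )


# ---------------------------------------------------------------------------
# Solving
# ---------------------------------------------------------------------------

@dataclass
class Solution:
    """One drug combination returned by the solver (or the oracle search)."""

    used_drugs: frozenset[str]
    objective: str
    status: str  # optimal | infeasible | time_limit
    objective_value: float = float("nan")
    sigma_milp: float = float("nan")
    sigma_oracle: float = float("nan")
    inner_max: float = float("nan")
    blocked_flags: dict[str, bool] = field(default_factory=dict)
    oracle_report: SideEffectReport | None = None

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "status": self.status,
            "used_drugs": sorted(self.used_drugs),
            "sigma_oracle": self.sigma_oracle,
            "sigma_milp": self.sigma_milp,
            "inner_max": self.inner_max,
        }


_STATUS = {0: "optimal", 1: "time_limit", 2: "infeasible", 3: "infeasible", 4: "error"}


def _extract_solution(instance: MilpInstance, res) -> Solution:
    status = _STATUS.get(res.status, "error")
    if res.x is None:
        return Solution(
            used_drugs=frozenset(), objective=instance.objective, status=status
        )
    x = res.x
    used = frozenset(k for k, idx in instance.d.items() if x[idx] < 0.5)
    blocked_flags = {
        rid: bool(x[instance.y[j]] < 0.5)
        for j, rid in enumerate(instance.model.reaction_ids)
    }
    sigma_milp = sum(
        instance.config.alpha_of(rid)
        for rid, stopped in blocked_flags.items()
        if stopped
    ) + sum(instance.catalog.beta.get(k, 0.0) for k in used)
    # big-M health check: a linearized product at its cap constrains the
    # certificate (plain delta at the bound is only dual degeneracy)
    tight = [
        instance.prog.names[idx]
        for idx, val in ((i, x[i]) for i in instance.z.values())
        if val > 0.99 * instance.config.delta_max
    ]
    if tight:
        logger.warning(
            "delta within 1%% of delta_max for %d dual variables "
            "(big-M possibly too tight): %s",
            len(tight),
            tight[:5],
        )
    return Solution(
        used_drugs=used,
        objective=instance.objective,
        status=status,
        objective_value=float(res.fun + instance.objective_constant),
        sigma_milp=float(sigma_milp),
        blocked_flags=blocked_flags,
    )


def solve_optimal_combination(
    model: MetabolicModel,
    catalog: DrugCatalog,
    objective: str,
    config: MilpConfig | None = None,
    forbidden_cuts: Sequence[Iterable[str]] = (),
    min_drugs: int = 0,
) -> Solution:
    """Solve for the minimal-side-effect drug set blocking the objective.

    On success the solution is certified twice: the independent inner LP
    confirms that the objective's maximal flux under the chosen drugs is
    below epsilon, and sigma is recomputed with the LP oracle (the value
    reported in ``sigma_oracle`` and used everywhere downstream).
    """
    config = config or MilpConfig()
    instance = build_milp(
        model, catalog, objective, config, forbidden_cuts, min_drugs
    )
    res = instance.prog.solve(mip_gap=config.mip_gap, time_limit=config.time_limit)
    sol = _extract_solution(instance, res)
    if sol.status != "optimal":
        return sol
    targets = frozenset().union(
        *(catalog.targets[k] for k in sol.used_drugs), frozenset()
    )
    sol.inner_max = blocking_oracle.max_flux_targets(model, targets, objective)
    if sol.inner_max >= config.epsilon:
        logger.error(
            "duality certificate violated: inner max %.3g >= epsilon for %s",
            sol.inner_max,
            objective,
        )
    report = blocking_oracle.side_effect(
        model, catalog, sol.used_drugs, objective, config.epsilon
    )
    sol.sigma_oracle = report.sigma
    sol.oracle_report = report
    return sol


def enumerate_solutions(
    model: MetabolicModel,
    catalog: DrugCatalog,
    objective: str,
    config: MilpConfig | None = None,
    max_solutions: int | None = None,
    min_drugs: int = 0,
) -> list[Solution]:
    """Hierarchical enumeration of optimal and suboptimal combinations.

    After each optimum D* the exclusion cut sum_{k in D*} d_k >= 1 is added,
    forbidding D* and all its supersets; iteration stops at infeasibility or
    after ``max_solutions``. Solutions come out in non-decreasing sigma_milp.
    """
    config = config or MilpConfig()
    out: list[Solution] = []
    cuts: list[frozenset[str]] = []
    while max_solutions is None or len(out) < max_solutions:
        sol = solve_optimal_combination(
            model, catalog, objective, config, forbidden_cuts=cuts, min_drugs=min_drugs
        )
        if sol.status != "optimal":
            break
        out.append(sol)
        if not sol.used_drugs:  # cannot cut the empty set; stop
            break
        cuts.append(sol.used_drugs)
    return out


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    """Independent checks of one MILP solution."""

    inner_max: float
    inner_ok: bool
    milp_stopped: frozenset[str]
    oracle_stopped: frozenset[str]
    discrepancies: frozenset[str]
    sigma_match: bool

    @property
    def passed(self) -> bool:
        return self.inner_ok and not self.discrepancies


def milp_stopped_set(
    model: MetabolicModel,
    blocked_flags: dict[str, bool],
    objective: str | None,
    baseline: frozenset[str],
) -> frozenset[str]:
    """Collapse per-column y flags to the comparable stopped-reaction set."""
    stopped = set()
    for p in model.parents():
        cols = model.columns_for(p)
        if all(blocked_flags[model.reaction_ids[j]] for j in cols):
            stopped.add(p)
    stopped -= baseline
    if objective is not None:
        stopped -= {parent_id(objective)}
    return frozenset(stopped)


def verify_solution(
    model: MetabolicModel,
    catalog: DrugCatalog,
    solution: Solution,
    config: MilpConfig | None = None,
) -> VerificationReport:
    """Guard the duality reformulation against the LP oracle.

    Checks (a) that the inner LP maximum of the objective flux under the used
    drugs is below epsilon, and (b) that the MILP's internal stopped-reaction
    set matches the per-reaction oracle; any mismatch (the simultaneity gap)
    is listed reaction by reaction.
    """
    if solution.status != "optimal":
        raise ValueError("can only verify an optimal solution")
    config = config or MilpConfig()
    targets = frozenset().union(
        *(catalog.targets[k] for k in solution.used_drugs), frozenset()
    )
    inner_max = blocking_oracle.max_flux_targets(model, targets, solution.objective)
    base = blocking_oracle.baseline_blocked(model, config.epsilon)
    oracle_stopped = (
        blocking_oracle.blocked_targets(model, targets, config.epsilon)
        - base
        - {parent_id(solution.objective)}
    )
    milp_stopped = milp_stopped_set(
        model, solution.blocked_flags, solution.objective, base
    )
    return VerificationReport(
        inner_max=inner_max,
        inner_ok=inner_max < config.epsilon,
        milp_stopped=milp_stopped,
        oracle_stopped=frozenset(oracle_stopped),
        discrepancies=frozenset(milp_stopped ^ oracle_stopped),
        sigma_match=len(milp_stopped) == len(oracle_stopped),
    )
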