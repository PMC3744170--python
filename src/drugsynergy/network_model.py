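"""Loading, validation and canonicalization of metabolic networks.

The optimization downstream works on flux-balance models in *non-negative*
form: every reversible reaction is decomposed into a forward/reverse pair of
irreversible reactions, so the steady-state flux space is

    H = {v : S v = 0, 0 <= v_j <= U_j}

with finite upper bounds ``U``. :class:`RawModel` is the as-read container
(bounds may be negative or infinite); :func:`split_reversible` produces the
canonical :class:`MetabolicModel`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

#: Suffix appended to the reverse twin of a split reversible reaction.
REVERSE_SUFFIX = "__rev"

#: Cap substituted for infinite bounds (duality needs finite capacities).
DEFAULT_CAP = 1000.0


class ModelFormatError(ValueError):
    """A model file could not be parsed or failed structural validation."""


def parent_id(reaction_id: str) -> str:
    """Collapse a split-reaction id to the id of its parent reaction."""
    if reaction_id.endswith(REVERSE_SUFFIX):
        return reaction_id[: -len(REVERSE_SUFFIX)]
    return reaction_id


@dataclass
class RawModel:
    """A metabolic network as read from disk, before canonicalization.

    Bounds are ``[lower, upper]`` per reaction; ``lower < 0`` marks a
    reversible reaction and infinities are allowed.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sparse.csc_matrix
    lower: np.ndarray
    upper: np.ndarray
    pathway: dict[str, str] = field(default_factory=dict)
    ec_numbers: dict[str, frozenset[str]] = field(default_factory=dict)
    compartment: dict[str, str] = field(default_factory=dict)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def validate(self) -> None:
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise ModelFormatError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ModelFormatError("duplicate metabolite ids")
        if np.any(self.lower > self.upper):
            bad = self.reaction_ids[int(np.argmax(self.lower > self.upper))]
            raise ModelFormatError(f"lower bound exceeds upper bound for {bad!r}")


@dataclass
class MetabolicModel:
    """Canonical irreversible-flux model.

    All reactions carry non-negative flux bounded by a finite ``upper``
    capacity; a reversible parent appears as two columns related through
    ``reverse_pair`` (an involution; the paired columns of ``S`` are exact
    negations of each other).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sparse.csc_matrix
    upper: np.ndarray
    pathway: dict[str, str] = field(default_factory=dict)
    ec_numbers: dict[str, frozenset[str]] = field(default_factory=dict)
    reverse_pair: dict[str, str] = field(default_factory=dict)
    exchange: set[str] = field(default_factory=set)
    compartment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {rid: j for j, rid in enumerate(self.reaction_ids)}

    # -- basic queries -----------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def index(self, reaction_id: str) -> int:
        return self._index[reaction_id]

    def parents(self) -> list[str]:
        """Collapsed reaction ids (each reversible pair counted once)."""
        seen: dict[str, None] = {}
        for rid in self.reaction_ids:
            seen.setdefault(parent_id(rid), None)
        return list(seen)

    def columns_for(self, parent: str) -> list[int]:
        """Column indices of all directions of a (possibly split) reaction."""
        cols = []
        if parent in self._index:
            cols.append(self._index[parent])
        twin = parent + REVERSE_SUFFIX
        if twin in self._index:
            cols.append(self._index[twin])
        if not cols:
            raise KeyError(f"unknown reaction {parent!r}")
        return cols

    def with_zeroed(self, parents: set[str]) -> "MetabolicModel":
        """Copy of the model with the given reactions' capacities set to 0."""
        upper = self.upper.copy()
        for p in parents:
            for j in self.columns_for(p):
                upper[j] = 0.0
        out = replace(self, upper=upper)
        return out

    # -- JSON caching ------------------------------------------------------
    def to_dict(self) -> dict:
        coo = self.S.tocoo()
        return {
            "metabolite_ids": self.metabolite_ids,
            "reaction_ids": self.reaction_ids,
            "S": [[int(i), int(j), float(x)] for i, j, x in zip(coo.row, coo.col, coo.data)],
            "upper": self.upper.tolist(),
            "pathway": self.pathway,
            "ec_numbers": {k: sorted(v) for k, v in self.ec_numbers.items()},
            "reverse_pair": self.reverse_pair,
            "exchange": sorted(self.exchange),
            "compartment": self.compartment,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicModel":
        n_m, n_r = len(d["metabolite_ids"]), len(d["reaction_ids"])
        rows, cols, data = [], [], []
        for i, j, x in d["S"]:
            rows.append(i), cols.append(j), data.append(x)
        S = sparse.csc_matrix((data, (rows, cols)), shape=(n_m, n_r))
        return cls(
            metabolite_ids=list(d["metabolite_ids"]),
            reaction_ids=list(d["reaction_ids"]),
            S=S,
            upper=np.asarray(d["upper"], dtype=float),
            pathway=dict(d.get("pathway", {})),
            ec_numbers={k: frozenset(v) for k, v in d.get("ec_numbers", {}).items()},
            reverse_pair=dict(d.get("reverse_pair", {})),
            exchange=set(d.get("exchange", [])),
            compartment=dict(d.get("compartment", {})),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "MetabolicModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(side: str, row: str) -> list[tuple[float, str]]:
    side = side.strip()
    if not side:
        return []
    terms = []
    for raw in side.split(" + "):
        raw = raw.strip()
        if not raw:
            continue
        m = _TERM_RE.match(raw)
        if m is None:
            raise ModelFormatError(f"cannot parse term {raw!r} in reaction {row!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        terms.append((coef, m.group(2)))
    return terms


def _parse_equation(eq: str, rid: str) -> dict[str, float]:
    if "->" not in eq:
        raise ModelFormatError(f"reaction {rid!r}: equation {eq!r} lacks '->'")
    lhs, rhs = eq.split("->", 1)
    stoich: dict[str, float] = {}
    for coef, met in _parse_side(lhs, rid):
        stoich[met] = stoich.get(met, 0.0) - coef
    for coef, met in _parse_side(rhs, rid):
        stoich[met] = stoich.get(met, 0.0) + coef
    return stoich


def _read_tabular(path, metabolites_path=None) -> RawModel:
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "equation", "lower", "upper"}
    missing = required - set(table.columns)
    if missing:
        raise ModelFormatError(f"tabular model missing columns: {sorted(missing)}")

    declared: list[str] | None = None
    compartment: dict[str, str] = {}
    if metabolites_path is not None:
        mtab = pd.read_csv(metabolites_path, sep="\t", dtype=str, keep_default_na=False)
        if "id" not in mtab.columns:
            raise ModelFormatError("metabolites table missing 'id' column")
        declared = list(mtab["id"])
        if "compartment" in mtab.columns:
            compartment = {m: c for m, c in zip(mtab["id"], mtab["compartment"]) if c}

    reaction_ids: list[str] = []
    stoichs: list[dict[str, float]] = []
    lower, upper = [], []
    pathway: dict[str, str] = {}
    ec: dict[str, frozenset[str]] = {}
    met_order: dict[str, int] = {m: i for i, m in enumerate(declared)} if declared else {}

    for _, row in table.iterrows():
        rid = row["id"]
        if rid in reaction_ids:
            raise ModelFormatError(f"duplicate reaction id {rid!r}")
        stoich = _parse_equation(row["equation"], rid)
        if declared is not None:
            for met in stoich:
                if met not in met_order:
                    raise ModelFormatError(
                        f"reaction {rid!r} references undeclared metabolite {met!r}"
                    )
        else:
            for met in stoich:
                met_order.setdefault(met, len(met_order))
        reaction_ids.append(rid)
        stoichs.append(stoich)
        try:
            lower.append(float(row["lower"]))
            upper.append(float(row["upper"]))
        except ValueError as exc:
            raise ModelFormatError(f"reaction {rid!r}: bad bounds") from exc
        if row.get("pathway", ""):
            pathway[rid] = row["pathway"]
        if row.get("ec", ""):
            ec[rid] = frozenset(e for e in row["ec"].split(";") if e)

    metabolite_ids = list(met_order)
    rows_i, cols_j, data = [], [], []
    for j, stoich in enumerate(stoichs):
        for met, coef in stoich.items():
            if coef != 0.0:
                rows_i.append(met_order[met]), cols_j.append(j), data.append(coef)
    S = sparse.csc_matrix(
        (data, (rows_i, cols_j)), shape=(len(metabolite_ids), len(reaction_ids))
    )
    raw = RawModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lower=np.asarray(lower),
        upper=np.asarray(upper),
        pathway=pathway,
        ec_numbers=ec,
        compartment=compartment,
    )
    raw.validate()
    return raw


def _read_sbml(path) -> RawModel:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from cobra.io import read_sbml_model

        cmodel = read_sbml_model(str(path))

    metabolite_ids = [m.id for m in cmodel.metabolites]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    reaction_ids, lower, upper = [], [], []
    pathway, ec, compartment = {}, {}, {}
    rows_i, cols_j, data = [], [], []
    for m in cmodel.metabolites:
        if m.compartment:
            compartment[m.id] = m.compartment
    for j, rxn in enumerate(cmodel.reactions):
        if rxn.id in set(reaction_ids):
            raise ModelFormatError(f"duplicate reaction id {rxn.id!r}")
        reaction_ids.append(rxn.id)
        lower.append(rxn.lower_bound)
        upper.append(rxn.upper_bound)
        if rxn.subsystem:
            pathway[rxn.id] = rxn.subsystem
        codes = rxn.annotation.get("ec-code", [])
        if isinstance(codes, str):
            codes = [codes]
        if codes:
            ec[rxn.id] = frozenset(codes)
        for met, coef in rxn.metabolites.items():
            rows_i.append(met_index[met.id]), cols_j.append(j), data.append(float(coef))
    S = sparse.csc_matrix(
        (data, (rows_i, cols_j)), shape=(len(metabolite_ids), len(reaction_ids))
    )
    raw = RawModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float),
        pathway=pathway,
        ec_numbers=ec,
        compartment=compartment,
    )
    raw.validate()
    return raw


def load_model(path, dialect: str = "tabular", metabolites_path=None) -> RawModel:
    """Read a model file into a :class:`RawModel`.

    Parameters
    ----------
    path : path-like
        Model file.
    dialect : {"tabular", "sbml"}
        ``tabular`` is a tab-separated reactions table with header columns
        ``id, equation, lower, upper[, pathway, ec]`` where the equation uses
        ``"a A + b B -> c C"`` syntax (an empty side marks an exchange);
        ``sbml`` accepts SBML Level 2/3.
    metabolites_path : path-like, optional
        Optional metabolites table (tabular dialect only); when given, every
        metabolite referenced by an equation must be declared in it.
    """
    if dialect == "tabular":
        raw = _read_tabular(path, metabolites_path)
    elif dialect == "sbml":
        raw = _read_sbml(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    logger.info(
        "loaded %s: %d metabolites, %d reactions", path, raw.n_metabolites, raw.n_reactions
    )
    return raw


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------

def split_reversible(raw: RawModel, default_cap: float = DEFAULT_CAP) -> MetabolicModel:
    """Decompose reversible reactions into irreversible forward/reverse pairs.

    A reaction with ``lower < 0`` becomes two reactions: the forward one keeps
    the original upper bound, the reverse one (id suffixed with
    ``REVERSE_SUFFIX``) gets ``U = -lower`` and the negated stoichiometric
    column; the two are registered in ``reverse_pair``. Infinite bounds are
    replaced by ``default_cap``, and positive lower bounds are relaxed to 0
    (the flux space downstream is the cone ``0 <= v <= U``).

    Idempotent on already-irreversible models; preserves the steady-state
    flux cone (net fluxes are in bijection).
    """
    raw.validate()
    S = raw.S.tocsc()
    reaction_ids: list[str] = []
    cols: list[np.ndarray] = []
    upper: list[float] = []
    reverse_pair: dict[str, str] = {}
    pathway: dict[str, str] = {}
    ec: dict[str, frozenset[str]] = {}

    def cap(x: float) -> float:
        return default_cap if np.isinf(x) else float(x)

    for j, rid in enumerate(raw.reaction_ids):
        col = S[:, j].toarray().ravel()
        ub = cap(max(raw.upper[j], 0.0))
        reaction_ids.append(rid)
        cols.append(col)
        upper.append(ub)
        if rid in raw.pathway:
            pathway[rid] = raw.pathway[rid]
        if rid in raw.ec_numbers:
            ec[rid] = raw.ec_numbers[rid]
        if raw.lower[j] < 0:
            rev = rid + REVERSE_SUFFIX
            reaction_ids.append(rev)
            cols.append(-col)
            upper.append(cap(-raw.lower[j]))
            reverse_pair[rid] = rev
            reverse_pair[rev] = rid
            if rid in raw.pathway:
                pathway[rev] = raw.pathway[rid]
            if rid in raw.ec_numbers:
                ec[rev] = raw.ec_numbers[rid]

    S_new = sparse.csc_matrix(np.column_stack(cols)) if cols else sparse.csc_matrix((raw.n_metabolites, 0))
    model = MetabolicModel(
        metabolite_ids=list(raw.metabolite_ids),
        reaction_ids=reaction_ids,
        S=S_new,
        upper=np.asarray(upper),
        pathway=pathway,
        ec_numbers=ec,
        reverse_pair=reverse_pair,
        compartment=dict(raw.compartment),
    )
    # boundary (exchange) reactions touch exactly one metabolite
    nnz = np.diff(model.S.tocsc().indptr)
    model.exchange = {rid for rid, n in zip(model.reaction_ids, nnz) if n <= 1}
    return model


def validate_model(model: MetabolicModel) -> list[str]:
    """Check the canonical-model invariants; return the list of violations.

    An empty report means the model is valid. Checks: unique ids, finite
    non-negative bounds, ``reverse_pair`` an involution with exactly negated
    stoichiometric columns, and no all-zero column outside the exchange set.
    """
    report: list[str] = []
    if len(set(model.reaction_ids)) != len(model.reaction_ids):
        report.append("duplicate reaction ids")
    if len(set(model.metabolite_ids)) != len(model.metabolite_ids):
        report.append("duplicate metabolite ids")
    for rid, u in zip(model.reaction_ids, model.upper):
        if not np.isfinite(u):
            report.append(f"non-finite upper bound for {rid}")
        elif u < 0:
            report.append(f"negative upper bound for {rid}")
    for rid, twin in model.reverse_pair.items():
        if model.reverse_pair.get(twin) != rid:
            report.append(f"reverse_pair not an involution at {rid}")
            continue
        if rid < twin:  # check each pair once
            a = model.S[:, model.index(rid)].toarray().ravel()
            b = model.S[:, model.index(twin)].toarray().ravel()
            if not np.allclose(a, -b):
                report.append(f"columns of pair ({rid}, {twin}) are not exact negations")
    dense_nnz = np.diff(model.S.tocsc().indptr)
    for rid, n in zip(model.reaction_ids, dense_nnz):
        if n == 0 and rid not in model.exchange:
            report.append(f"all-zero stoichiometric column for {rid} not flagged exchange")
    return report


# ---------------------------------------------------------------------------
# Writers (used by fixtures and round-trip tests)
# ---------------------------------------------------------------------------

def write_tabular(raw: RawModel, path) -> None:
    """Write a :class:`RawModel` in the tabular dialect."""
    met = raw.metabolite_ids
    S = raw.S.tocsc()
    with open(path, "w") as fh:
        fh.write("id\tequation\tlower\tupper\tpathway\tec\n")
        for j, rid in enumerate(raw.reaction_ids):
            col = S[:, j].toarray().ravel()
            lhs = " + ".join(
                (f"{-c:g} {met[i]}" if c != -1 else met[i])
                for i, c in enumerate(col)
                if c < 0
            )
            rhs = " + ".join(
                (f"{c:g} {met[i]}" if c != 1 else met[i])
                for i, c in enumerate(col)
                if c > 0
            )
            eq = f"{lhs} -> {rhs}".strip()
            ecs = ";".join(sorted(raw.ec_numbers.get(rid, ())))
            fh.write(
                f"{rid}\t{eq}\t{raw.lower[j]:g}\t{raw.upper[j]:g}"
                f"\t{raw.pathway.get(rid, '')}\t{ecs}\n"
            )


def write_sbml(raw: RawModel, path) -> None:
    """Write a :class:`RawModel` as SBML Level 3 (via cobrapy)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import cobra
        from cobra.io import write_sbml_model

        cmodel = cobra.Model("model")
        mets = {}
        for mid in raw.metabolite_ids:
            m = cobra.Metabolite(mid, compartment=raw.compartment.get(mid, "c"))
            mets[mid] = m
        cmodel.add_metabolites(list(mets.values()))
        S = raw.S.tocsc()
        rxns = []
        for j, rid in enumerate(raw.reaction_ids):
            rxn = cobra.Reaction(rid)
            rxn.lower_bound = float(raw.lower[j])
            rxn.upper_bound = float(raw.upper[j])
            if rid in raw.pathway:
                rxn.subsystem = raw.pathway[rid]
            rxns.append(rxn)
        cmodel.add_reactions(rxns)
        for j, rxn in enumerate(rxns):
            col = S[:, j].toarray().ravel()
            rxn.add_metabolites(
                {mets[raw.metabolite_ids[i]]: float(c) for i, c in enumerate(col) if c != 0}
            )
            if raw.reaction_ids[j] in raw.ec_numbers:
                rxn.annotation["ec-code"] = sorted(raw.ec_numbers[raw.reaction_ids[j]])
        write_sbml_model(cmodel, str(path))
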