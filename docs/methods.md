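# Methods

## Problem and formulation

The package answers: *which subset of a drug catalog abolishes the flux of a
chosen metabolic reaction while disabling as little of the rest of the
network as possible?* It works on flux-balance models — steady-state flux
cones `H = {v : Sv = 0, 0 ≤ v ≤ U}` — after canonicalization to non-negative
fluxes (every reversible reaction split into a forward/reverse twin pair).
Inhibition is all-or-none: a used drug forces each of its target reactions to
zero flux (`v_j ≤ U_j d_k`, binary `d_k = 0` when drug `k` is used). Partial
inhibition, dosing, kinetics and concentration-level interactions are out of
scope, as is any interaction mediated by metabolite accumulation on a linear
pathway — the steady-state formalism cannot see those.

Because no consensus "wild-type" flux objective exists for human cells,
MOMA/ROOM-style perturbation measures are unusable here; the side effect is
instead the *count of reactions made unable to carry flux*, plus a penalty
for each used drug's non-metabolic targets:

    σ(D) = Σ_j α_j (1 − y_j) + Σ_k β_k (1 − d_k),
    β_k  = β̄ · (# non-metabolic targets of drug k).

`y_j = 1` iff reaction `j` carries at least ε flux; the linear encoding
`ε y_j ≤ v_j ≤ U_j y_j` makes any feasible flux either 0 or ≥ ε, and the
pair constraint `y_j + y_l ≤ 1` prevents a reversible reaction from being
counted active twice. `α_j = 1` for all reactions (configurable; nothing in
the method requires non-uniform weights, so uniform is the default).

The bilevel program — outer: minimize σ over drug sets; inner: maximize
`v_obj` over `H(D)`, required to reach 0 — is collapsed by LP strong duality:
dual feasibility rows `(Sᵀμ)_j + λ_j + Σ_{k∈T_j} δ_jk ≥ c_j` (1 for the
objective column, 0 otherwise) plus the equality of the inner primal and
dual objectives, `v_obj = Σ_j U_j λ_j + Σ_{(j,k)} U_j z_jk`, where one dual
δ (and one linearized product z) exists per (target reaction, drug)
coupling constraint. Since `v_obj = 0` and every right-hand term is
non-negative, the equality is a Farkas-type certificate that the inner
maximum is exactly zero. Products `δ·d` are linearized exactly with
`0 ≤ z ≤ δ_max d` and `δ − δ_max(1−d) ≤ z ≤ δ`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 0.1 | flux (arbitrary units) below which a reaction counts as stopped; must be far below the smallest relevant capacity |
| `b` | 0.001 | per-unused-drug bonus; removes redundant drugs from optima without ever outweighing a genuine σ difference |
| `delta_max` | 1000 | big-M bound on the duals δ; only needs to exceed the magnitude of some optimal dual, which is O(1) for unit-scale stoichiometries |
| `alpha` | 1 per reaction | per-reaction weight of the stopped count |
| `default_cap` | 1000 | finite capacity substituted for infinite bounds (duality needs finite U) |
| `mip_gap` | 0 | relative MIP gap; kept at 0 because σ differences can be as small as β̄/n_pairs |

A too-small `delta_max` manifests as spurious infeasibility (the certificate
cannot be expressed), not as a wrong optimum; a post-solve check warns when a
linearized product sits at its cap.

## Oracle, and what "blocked" means

All reported σ values, blocked sets and synergy sets come from a direct LP
oracle, independent of the MILP: a (collapsed) reaction is blocked iff no
direction of it can reach ε net flux (strict `< ε`, with a 1e-6 LP tolerance
subtracted). Reactions blocked in the unperturbed network and the objective
itself are excluded from all counts.

Two deliberate semantic choices:

* **Net flux for split pairs.** The forward/reverse twins of a reversible
  reaction admit an arbitrary futile cycle (equal flux both ways, zero net)
  that is an artifact of the splitting, not activity. The oracle therefore
  maximizes each direction with the twin held at zero, and witness scans use
  `|v_fwd − v_rev|`. Consistently, a reversible *objective* receives one
  strong-duality certificate per net direction (the twin's capacity zeroed
  in that certificate); an irreversible objective gets the standard single
  certificate. Multi-reaction thermodynamically infeasible loops are *not*
  handled (loop-law corrections are out of scope): a reaction sustained only
  by a loop through other reversible reactions still counts as active.
* **Per-reaction vs simultaneous counting (the simultaneity gap).** The
  oracle asks each reaction independently whether it *could* carry ε flux;
  the MILP's internal `Σ(1−y)` counts one simultaneous flux pattern. On
  capacity-tight networks a shared bottleneck can sustain each branch alone
  but not all at once, so the MILP over-counts stopped reactions relative to
  the oracle. `verify_solution` detects exactly this (the packaged
  `bottleneck_fixture` triggers it by construction), and the oracle value is
  authoritative in all reports. With capacities orders of magnitude above ε
  — the regime of the bundled generators and of genome-scale models with
  default bounds — the two counts coincide.

`β̄` is estimated as the mean, over all (drug, target-reaction) pairs of the
catalog, of the number of reactions newly blocked when that single target is
inhibited. Averaging over pairs (rather than over drugs or over distinct
targets) uses every single-target inhibition exactly once; for single-target
drugs all three readings coincide.

## Enumeration and screening

Suboptimal solutions are enumerated by re-solving after appending
`Σ_{k∈D*} d_k ≥ 1` for each previous optimum `D*` — this forbids `D*` and
all supersets, consistent with the redundancy-exclusion term — until the
MILP is infeasible. In the whole-network screen, each reaction is tried as
objective; the multi-drug arm is the MILP restricted to ≥ 2 used drugs and
the single-drug arm is read off pre-computed per-drug blocked sets; outcomes
are classified as `single_only`, `new_inhibition`, `more_selective`,
`less_selective` or `unblockable` by comparing oracle σ values. The summary
ratio column is `100·|Y|/σ` truncated (not rounded) to one decimal place.

Synergy profiles (the sets Y) are compared with the Jaccard distance by
default — Y sets vary over orders of magnitude in size, and Jaccard groups
by shared mechanism rather than by size; Hamming on the 0/1 vectors is
available. Trees use average linkage (neighbor joining optional); the flat
class labels come from cutting the average-linkage tree at a configurable
threshold, since any particular class count is an observation about one
dataset, not part of the method.

## Two-network variant

One MILP couples a *target* model (full primal + duality blocks, objective
forced to zero) and a *reference* model (primal + y indicators only) through
shared drug variables; the outer objective counts σ on the reference network
only. Preservation of the reference metabolism is soft (minimized, not
constrained) — solutions with nonzero reference side effect remain feasible.
The reference reaction corresponding to the objective (via the
reaction-correspondence map) is excluded from the reference σ, which makes
the solver reduce exactly to the single-network one when the two models and
the objective coincide; when no correspondence exists for the objective,
every stopped reference reaction counts. The additional-target screen
deletes one candidate reaction from both networks (capacity set to zero) and
re-solves, flagging candidates whose deletion alone kills the objective
(`deletion_lethal`), enables a previously impossible inhibition
(`new_inhibition`), or improves σ.

## Synthetic data

`toy_instance` reconstructs the canonical didactic instance from its stated
behavior: a 10-reaction branched network where the objective `v10` is fed by
two branches drugged at `v4` and `v7`, a sole upstream conduit is drugged at
`v2`, and side exports keep the branch drugs individually harmless. Only the
behavioral facts are contractual (single drugs fail; `v2` kills everything;
the pair is σ-optimal); the exact topology (side exports, capacities U = 10)
is this package's reconstruction. All β = 0 there.

`random_instance` generates layered branched-pathway DAGs (uptake exchanges,
unit-stoichiometry internal conversions with occasional branching, an export
for every producible metabolite) with capacities 100–1000 ≫ ε, a ~20 %
reversible fraction, and 6 drugs with 1–3 random internal targets and 0–2
non-metabolic targets — sized (≤ 40 split reactions, ≤ 8 drugs) so exhaustive
subset search remains a feasible independent oracle. These instances emulate
the *structure* that makes the optimization hard (branch redundancy, shared
intermediates, overlapping target sets) but not the scale, compartments,
cofactor coupling or bound heterogeneity of genome-scale reconstructions: a
green equivalence suite establishes correctness of the reformulation, not
performance or biological fidelity at genome scale.

## Numerical choices

LPs and MILPs are solved with HiGHS (single-threaded, deterministic);
binaries are decoded at 0.5. Blocked-set computation reuses LP witnesses
(any reaction seen carrying ≥ ε in an optimum is marked active without its
own LP). Brute-force search memoizes feasibility and σ by the union of
forced-off targets, and breaks σ ties by fewer drugs, then lexicographic
drug ids; the MILP's `−b Σ d_k` term realizes the same cardinality
preference, so tied optima may differ in identity but never in σ. Exchange
reactions are detected as single-metabolite columns. Degenerate inputs:
an objective blocked without any drug raises a dedicated error; an empty
drug catalog yields infeasibility; drugs whose annotations resolve to no
model reaction are dropped with a warning.

## Known limitations

* All-or-none inhibition only; no dose–response.
* Loop-law violations through distinct reversible reactions are not removed.
* The reference-network formulation of the selective variant is a soft
  minimization; hard preservation constraints are not offered.
* The screen solves one MILP per reaction; at genome scale this is hours of
  CPU, and the package does not parallelize it.
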