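"""Linear-programming core: FBA, FVA and blocked-flux detection.

Flux balance analysis solves

    max (or min)  c . v
    subject to    S . v = 0,   lb <= v <= ub

where S is the stoichiometric matrix (rows = metabolites, columns =
reactions), v the flux vector in mmol/gDW/h, and c the objective
(normally the biomass pseudo-reaction).  All programs are solved with
the HiGHS solvers behind ``scipy.optimize.linprog``.

Numerical conventions: feasibility/optimality tolerance 1e-6, and a
flux is "zero" when its magnitude is below 1e-6.  FBA returns one
optimizer-chosen vertex; every contract downstream is stated on the
objective value and on FVA ranges, never on a particular flux vector,
because alternate optima are ubiquitous in genome-scale models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "TOLERANCE",
    "StoichiometricSystem",
    "FluxSolution",
    "FVAResult",
    "SolverError",
    "build_system",
    "solve_fba",
    "run_fva",
    "find_blocked_reactions",
    "find_blocked_metabolites",
]

#: feasibility / optimality / zero-flux tolerance for all LPs
TOLERANCE = 1e-6


class SolverError(RuntimeError):
    """Raised when the LP optimizer fails for a reason other than
    infeasibility or unboundedness (which are reported as statuses)."""


@dataclass
class StoichiometricSystem:
    """The assembled LP data of a model.

    Bound arrays are copies: mutating them (media, knockouts, fixed
    biomass) never touches the originating model.
    """

    S: sparse.csr_matrix
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    row_index: dict[str, int] = field(repr=False)
    col_index: dict[str, int] = field(repr=False)

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    def copy(self) -> "StoichiometricSystem":
        return StoichiometricSystem(
            S=self.S,
            lower=self.lower.copy(),
            upper=self.upper.copy(),
            objective=self.objective.copy(),
            reaction_ids=self.reaction_ids,
            metabolite_ids=self.metabolite_ids,
            row_index=self.row_index,
            col_index=self.col_index,
        )

    def with_bounds(self, overrides: dict[str, tuple[float, float]]) -> "StoichiometricSystem":
        """A copy with per-reaction (lower, upper) bound overrides."""
        out = self.copy()
        for rid, (lo, hi) in overrides.items():
            j = self.col_index[rid]
            out.lower[j] = lo
            out.upper[j] = hi
        return out


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    ranges: dict[str, tuple[float, float]]
    fraction_of_optimum: float

    def minimum(self, rid: str) -> float:
        return self.ranges[rid][0]

    def maximum(self, rid: str) -> float:
        return self.ranges[rid][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(rid, lo, hi) for rid, (lo, hi) in self.ranges.items()],
            columns=["reaction", "minimum", "maximum"],
        )


def build_system(model: MetabolicModel) -> StoichiometricSystem:
    """Assemble the sparse stoichiometric system of a model.

    One row per metabolite and one column per reaction, in model order;
    orphan metabolites keep their (all-zero) rows.
    """
    row_index = {m.id: i for i, m in enumerate(model.metabolites)}
    col_index = {r.id: j for j, r in enumerate(model.reactions)}
    n_met, n_rxn = len(row_index), len(col_index)

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    lower = np.zeros(n_rxn)
    upper = np.zeros(n_rxn)
    objective = np.zeros(n_rxn)
    for j, rxn in enumerate(model.reactions):
        lower[j] = rxn.lower_bound
        upper[j] = rxn.upper_bound
        objective[j] = rxn.objective_coefficient
        for met_id, coeff in rxn.stoichiometry.items():
            rows.append(row_index[met_id])
            cols.append(j)
            data.append(coeff)

    S = sparse.csr_matrix((data, (rows, cols)), shape=(n_met, n_rxn))
    return StoichiometricSystem(
        S=S,
        lower=lower,
        upper=upper,
        objective=objective,
        reaction_ids=[r.id for r in model.reactions],
        metabolite_ids=[m.id for m in model.metabolites],
        row_index=row_index,
        col_index=col_index,
    )


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(
    system: StoichiometricSystem,
    c: np.ndarray,
    sense: str,
    extra_A_ub: sparse.spmatrix | None = None,
    extra_b_ub: np.ndarray | None = None,
) -> FluxSolution:
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"sense must be 'maximize' or 'minimize', got {sense!r}")
    sign = -1.0 if sense == "maximize" else 1.0
    n = system.n_reactions
    result = linprog(
        sign * c,
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        A_eq=system.S if system.n_metabolites else None,
        b_eq=np.zeros(system.n_metabolites) if system.n_metabolites else None,
        bounds=np.column_stack([system.lower, system.upper]) if n else [],
        method="highs",
    )
    status = _STATUS.get(result.status, "numerical")
    if status in ("iteration_limit", "numerical"):
        raise SolverError(f"LP solver failed: {result.message}")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"), fluxes={})
    v = result.x if result.x is not None else np.zeros(n)
    fluxes = dict(zip(system.reaction_ids, (float(x) for x in v)))
    return FluxSolution(status="optimal", objective_value=float(c @ v), fluxes=fluxes)


def solve_fba(system: StoichiometricSystem, sense: str = "maximize") -> FluxSolution:
    """Solve flux balance analysis on the assembled system.

    Raises ``ValueError`` if the objective vector is all-zero (there is
    nothing to optimize) and ``SolverError`` on numerical failure.
    """
    if not np.any(system.objective):
        raise ValueError("objective vector is zero; set an objective reaction first")
    return _solve(system, system.objective, sense)


def _objective_constraint(
    system: StoichiometricSystem, optimum: float, fraction: float
) -> tuple[sparse.spmatrix, np.ndarray]:
    # c.v >= fraction * Z*  encoded as  -c.v <= -fraction * Z*
    A = sparse.csr_matrix(-system.objective.reshape(1, -1))
    b = np.array([-fraction * optimum])
    return A, b


def run_fva(
    system: StoichiometricSystem,
    fraction_of_optimum: float = 1.0,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Flux variability analysis.

    For each requested reaction the flux is minimized and maximized
    subject to the objective being held at ``fraction_of_optimum``
    times its FBA optimum Z* (constraint ``c.v >= fraction * Z*`` for a
    maximization objective, applied unchanged when Z* < 0).  The
    default fraction 1.0 explores only alternate optima; fraction 0
    explores the whole feasible cone.
    """
    base = solve_fba(system)
    if not base.optimal:
        raise SolverError(f"FVA base problem is {base.status}")
    A_ub, b_ub = _objective_constraint(system, base.objective_value, fraction_of_optimum)
    # guard against tolerance-level infeasibility at fraction exactly 1.0
    b_ub = b_ub + TOLERANCE

    targets = reactions if reactions is not None else list(system.reaction_ids)
    ranges: dict[str, tuple[float, float]] = {}
    n = system.n_reactions
    for rid in targets:
        j = system.col_index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve(system, c, "minimize", A_ub, b_ub)
        hi = _solve(system, c, "maximize", A_ub, b_ub)
        if not (lo.optimal and hi.optimal):
            raise SolverError(f"FVA subproblem for {rid} was {lo.status}/{hi.status}")
        ranges[rid] = (lo.objective_value, hi.objective_value)
    return FVAResult(ranges=ranges, fraction_of_optimum=fraction_of_optimum)


def find_blocked_reactions(
    system: StoichiometricSystem, tolerance: float = TOLERANCE
) -> set[str]:
    """Reactions that can carry no flux in any feasible steady state.

    Variability is assessed on the system exactly as bounded (the
    model's declared exchange bounds, no objective constraint): a
    reaction is blocked iff both its flux minimum and maximum are
    within tolerance of zero.
    """
    n = system.n_reactions
    blocked: set[str] = set()
    for rid in system.reaction_ids:
        j = system.col_index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        hi = _solve(system, c, "maximize")
        if hi.status == "unbounded" or abs(hi.objective_value) > tolerance:
            continue
        if system.lower[j] >= -tolerance:
            # irreversible: maximum ~ 0 already pins the flux to zero
            blocked.add(rid)
            continue
        lo = _solve(system, c, "minimize")
        if lo.status != "unbounded" and abs(lo.objective_value) <= tolerance:
            blocked.add(rid)
    return blocked


def find_blocked_metabolites(
    model: MetabolicModel, blocked_reactions: set[str]
) -> set[str]:
    """Metabolites participating only in blocked reactions.

    Such a metabolite can never be produced or consumed in any steady
    state.  Metabolites that participate in no reaction at all are
    blocked by the same criterion (vacuously).
    """
    blocked: set[str] = set()
    for met in model.metabolites:
        touching = model.reactions_of_metabolite(met.id)
        if all(r.id in blocked_reactions for r in touching):
            blocked.add(met.id)
    return blocked
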