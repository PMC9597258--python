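"""Independent brute-force oracles used to cross-check the LP engine.

These deliberately avoid the package's own system-assembly and GPR
machinery: the LP is formulated dense, straight from the model's
reaction list, and boolean GPR rules are re-evaluated by translating
the serialized rule into a Python expression.  They are only tractable
for the small synthetic fixtures.
"""

from __future__ import annotations

import re

import numpy as np
from scipy.optimize import linprog

TOL = 1e-6


def dense_fba_optimum(model, disabled: set[str] = frozenset()) -> float:
    """FBA optimum from a dense, independently assembled LP.

    ``disabled`` reactions are dropped from the formulation entirely
    (not zero-bounded), so the oracle exercises a different code path
    than bound-override knockouts.
    """
    reactions = [r for r in model.reactions if r.id not in disabled]
    met_ids = [m.id for m in model.metabolites]
    row = {mid: i for i, mid in enumerate(met_ids)}
    A = np.zeros((len(met_ids), len(reactions)))
    lb = np.zeros(len(reactions))
    ub = np.zeros(len(reactions))
    c = np.zeros(len(reactions))
    for j, rxn in enumerate(reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        c[j] = rxn.objective_coefficient
        for mid, coeff in rxn.stoichiometry.items():
            A[row[mid], j] = coeff
    res = linprog(
        -c,
        A_eq=A,
        b_eq=np.zeros(len(met_ids)),
        bounds=list(zip(lb, ub)),
        method="highs-ds",
    )
    if res.status != 0:
        return 0.0
    return float(c @ res.x)


def dense_flux_extremum(model, rxn_id: str, sense: str) -> float | None:
    """Min or max flux of one reaction under steady state; None if infeasible."""
    reactions = model.reactions
    met_ids = [m.id for m in model.metabolites]
    row = {mid: i for i, mid in enumerate(met_ids)}
    A = np.zeros((len(met_ids), len(reactions)))
    bounds = []
    c = np.zeros(len(reactions))
    for j, rxn in enumerate(reactions):
        bounds.append((rxn.lower_bound, rxn.upper_bound))
        if rxn.id == rxn_id:
            c[j] = 1.0
        for mid, coeff in rxn.stoichiometry.items():
            A[row[mid], j] = coeff
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c, A_eq=A, b_eq=np.zeros(len(met_ids)), bounds=bounds, method="highs-ds"
    )
    if res.status != 0:
        return None
    return float(c @ res.x)


def brute_force_blocked(model) -> set[str]:
    """Blocked = max |v| over the feasible region is ~0, per reaction."""
    blocked = set()
    for rxn in model.reactions:
        hi = dense_flux_extremum(model, rxn.id, "max")
        lo = dense_flux_extremum(model, rxn.id, "min")
        if hi is not None and lo is not None and max(abs(hi), abs(lo)) <= TOL:
            blocked.add(rxn.id)
    return blocked


_TOKEN = re.compile(r"[A-Za-z_][\w.]*|\(|\)")


def python_eval_gpr(rule: str, knocked_out: set[str]) -> bool:
    """Evaluate a serialized GPR rule with Python's own boolean logic."""
    if not rule.strip():
        return True

    def sub(match: re.Match) -> str:
        tok = match.group(0)
        if tok in ("(", ")"):
            return tok
        if tok.lower() in ("and", "or"):
            return tok.lower()
        return "False" if tok in knocked_out else "True"

    return bool(eval(_TOKEN.sub(sub, rule)))  # noqa: S307 - controlled input


def brute_force_essential_genes(model, medium_limits: dict[str, float]) -> set[str]:
    """Per-gene rebuild-and-resolve essentiality oracle.

    For every gene: re-evaluate each reaction's serialized GPR with
    Python's boolean operators, drop disabled reactions from a freshly
    built model copy, apply the medium as plain bound edits, and solve
    the dense LP from scratch.
    """
    work = model.copy()
    exchange_ids = {r.id for r in work.exchanges()}
    for rxn in work.reactions:
        if rxn.id in exchange_ids:
            rxn.lower_bound = -medium_limits.get(rxn.id, 0.0)
    essential = set()
    for gene in work.genes:
        disabled = {
            r.id
            for r in work.reactions
            if r.gpr is not None
            and not python_eval_gpr(r.gpr.to_string(), {gene.id})
        }
        if dense_fba_optimum(work, disabled) < TOL:
            essential.add(gene.id)
    return essential
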