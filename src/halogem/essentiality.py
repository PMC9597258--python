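"""Single-gene knockouts and the essentiality screen.

A knockout disables every reaction whose GPR rule evaluates false once
the gene is removed; growth is then re-optimized with FBA.  A gene is
essential when the knockout drops predicted growth below the
zero-growth threshold (default 1e-6 1/h; some studies prefer 1-5% of
the wildtype rate, so the threshold is a parameter).  The result
depends only on objective values, never on which optimal flux vector
the solver happened to return, so the essential set is deterministic
across runs and reaction orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gpr import evaluate_gpr
from .lp import build_system, solve_fba
from .model import MetabolicModel
from .phenotype import GROWTH_THRESHOLD, Medium, set_medium

__all__ = ["EssentialityResult", "apply_knockout", "single_gene_essentiality"]


@dataclass
class EssentialityResult:
    growth: dict[str, float]  # gene id -> growth after knockout, 1/h
    essential: set[str]
    threshold: float
    wildtype_growth: float

    def is_essential(self, gene_id: str) -> bool:
        return gene_id in self.essential

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (gid, g, gid in self.essential) for gid, g in self.growth.items()
        ]
        return pd.DataFrame(rows, columns=["gene", "growth", "essential"])


def apply_knockout(
    model: MetabolicModel, genes: set[str]
) -> dict[str, tuple[float, float]]:
    """Bound overrides realizing a (multi-)gene knockout.

    Every reaction whose GPR evaluates false with the given genes
    removed is clamped to (0, 0); reactions whose rule still holds (or
    that have no rule) are untouched.  The model itself is never
    mutated.  Unknown gene ids are a lookup error.
    """
    known = {g.id for g in model.genes}
    unknown = set(genes) - known
    if unknown:
        raise KeyError(f"unknown gene id(s): {', '.join(sorted(unknown))}")
    overrides: dict[str, tuple[float, float]] = {}
    for rxn in model.reactions:
        if rxn.gpr is not None and not evaluate_gpr(rxn.gpr, genes):
            overrides[rxn.id] = (0.0, 0.0)
    return overrides


def single_gene_essentiality(
    model: MetabolicModel,
    medium: Medium,
    threshold: float = GROWTH_THRESHOLD,
) -> EssentialityResult:
    """Knock out each gene in turn and record the re-optimized growth.

    Covers every gene of the model: genes referenced by no GPR are
    trivially non-essential and still appear in the result.  Knockouts
    that disable the same reaction set share one LP solve.
    """
    system = build_system(model).with_bounds(set_medium(model, medium))
    wildtype = solve_fba(system)
    if not wildtype.optimal or wildtype.objective_value < threshold:
        raise ValueError(
            "wildtype does not grow on the given medium; fix the medium before "
            "screening essentiality"
        )

    growth: dict[str, float] = {}
    essential: set[str] = set()
    cache: dict[frozenset[str], float] = {frozenset(): wildtype.objective_value}
    for gene in model.genes:
        overrides = apply_knockout(model, {gene.id})
        key = frozenset(overrides)
        if key not in cache:
            solution = solve_fba(system.with_bounds(overrides))
            cache[key] = solution.objective_value if solution.optimal else 0.0
        g = cache[key]
        growth[gene.id] = g
        if g < threshold:
            essential.add(gene.id)
    return EssentialityResult(
        growth=growth,
        essential=essential,
        threshold=threshold,
        wildtype_growth=wildtype.objective_value,
    )
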