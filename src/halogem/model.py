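"""Domain model of a genome-scale metabolic network.

A :class:`MetabolicModel` is the in-memory form of an SBML Level 3 (FBC)
model: metabolites partitioned into compartments, reactions with flux
bounds in mmol/gDW/h and signed stoichiometric coefficients (negative =
consumed), boolean gene--protein--reaction (GPR) rules, and a linear
objective (normally the biomass pseudo-reaction, whose flux is the growth
rate in 1/h).  No unit conversion is ever performed.

Sign convention for boundary reactions: negative flux is uptake,
positive flux is secretion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .gpr import GPRExpression

__all__ = [
    "Metabolite",
    "Gene",
    "Reaction",
    "MetabolicModel",
    "ValidationIssue",
    "validate_model",
    "parse_formula",
    "DEFAULT_UPPER",
]

#: Conventional BiGG-style default magnitude for unspecified flux bounds.
DEFAULT_UPPER = 1000.0

_EXCHANGE_PREFIXES = ("EX_", "R_EX_")
_DEMAND_PREFIXES = ("DM_", "R_DM_")
_SINK_PREFIXES = ("SK_", "R_SK_")

SBO_EXCHANGE = "SBO:0000627"
SBO_DEMAND = "SBO:0000628"
SBO_SINK = "SBO:0000632"
SBO_BIOMASS = "SBO:0000629"

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C6H12O6`` into counts.

    Raises ``ValueError`` on anything that is not a plain sequence of
    element symbols with optional integer counts (no parentheses, no
    charges -- charges live on the metabolite itself).
    """
    pos = 0
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {formula!r} at position {pos}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r} at position {pos}")
    return counts


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    def elements(self) -> dict[str, int] | None:
        """Elemental composition, or None when no/invalid formula."""
        if not self.formula:
            return None
        try:
            return parse_formula(self.formula)
        except ValueError:
            return None


@dataclass
class Gene:
    id: str
    name: str | None = None


@dataclass
class Reaction:
    """One reaction: stoichiometry maps metabolite id -> signed coefficient."""

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_UPPER
    upper_bound: float = DEFAULT_UPPER
    gpr: GPRExpression | None = None
    objective_coefficient: float = 0.0
    sbo_term: str | None = None
    subsystem: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def is_boundary(self) -> bool:
        """True when the reaction touches exactly one metabolite."""
        return len(self.stoichiometry) == 1

    def is_exchange(self) -> bool:
        if self.sbo_term == SBO_EXCHANGE:
            return True
        if self.sbo_term in (SBO_DEMAND, SBO_SINK, SBO_BIOMASS):
            return False
        return self.is_boundary() and self.id.startswith(_EXCHANGE_PREFIXES)

    def is_demand(self) -> bool:
        if self.sbo_term == SBO_DEMAND:
            return True
        return self.is_boundary() and self.id.startswith(_DEMAND_PREFIXES)

    def is_sink(self) -> bool:
        if self.sbo_term == SBO_SINK:
            return True
        return self.is_boundary() and self.id.startswith(_SINK_PREFIXES)

    def is_biomass(self) -> bool:
        return self.sbo_term == SBO_BIOMASS or self.objective_coefficient != 0.0

    def mass_balance_exempt(self) -> bool:
        """Boundary and biomass pseudo-reactions are not mass balanced."""
        return (
            self.is_boundary()
            or self.is_exchange()
            or self.is_demand()
            or self.is_sink()
            or self.is_biomass()
        )

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)
    compartments: set[str] = field(default_factory=set)
    name: str = ""

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(f"no gene {gene_id!r} in model {self.id!r}")

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index()

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index()

    def _met_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    # -- views -----------------------------------------------------------
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange()]

    def objective_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.objective_coefficient != 0.0]

    def biomass_reaction(self) -> Reaction:
        objs = self.objective_reactions()
        if len(objs) != 1:
            raise ValueError(
                f"model {self.id!r} has {len(objs)} objective reactions; expected 1"
            )
        return objs[0]

    def reactions_of_metabolite(self, met_id: str) -> list[Reaction]:
        return [r for r in self.reactions if met_id in r.stoichiometry]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=[replace(g) for g in self.genes],
            compartments=set(self.compartments),
            name=self.name,
        )


@dataclass
class ValidationIssue:
    severity: str  # "error" or "warning"
    entity: str
    message: str


def _duplicates(ids: list[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


def validate_model(model: MetabolicModel) -> list[ValidationIssue]:
    """Structural and stoichiometric sanity report.

    Checks: duplicate ids, bound violations (lower > upper), dangling
    metabolite/gene references, empty stoichiometry on non-boundary
    reactions, elemental mass imbalance (only when every participant has
    a parseable formula) and charge imbalance (only when every
    participant has a charge).  Boundary pseudo-reactions -- exchange,
    demand, sink and biomass -- are exempt from balance checks.
    """
    issues: list[ValidationIssue] = []
    for dup in _duplicates([m.id for m in model.metabolites]):
        issues.append(ValidationIssue("error", dup, "duplicate metabolite id"))
    for dup in _duplicates([r.id for r in model.reactions]):
        issues.append(ValidationIssue("error", dup, "duplicate reaction id"))
    for dup in _duplicates([g.id for g in model.genes]):
        issues.append(ValidationIssue("error", dup, "duplicate gene id"))

    met_ids = {m.id for m in model.metabolites}
    gene_ids = {g.id for g in model.genes}

    for met in model.metabolites:
        if not met.id:
            issues.append(ValidationIssue("error", "<empty>", "empty metabolite id"))
        if model.compartments and met.compartment not in model.compartments:
            issues.append(
                ValidationIssue(
                    "error", met.id, f"undeclared compartment {met.compartment!r}"
                )
            )

    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            issues.append(
                ValidationIssue(
                    "error",
                    rxn.id,
                    f"lower bound {rxn.lower_bound} exceeds upper bound {rxn.upper_bound}",
                )
            )
        if not rxn.stoichiometry and not rxn.is_exchange():
            issues.append(
                ValidationIssue("error", rxn.id, "empty stoichiometry on non-exchange reaction")
            )
        for met_id in rxn.stoichiometry:
            if met_id not in met_ids:
                issues.append(
                    ValidationIssue(
                        "error", rxn.id, f"references undeclared metabolite {met_id!r}"
                    )
                )
        if rxn.gpr is not None:
            for gid in sorted(rxn.gpr.genes()):
                if gid not in gene_ids:
                    issues.append(
                        ValidationIssue(
                            "error", rxn.id, f"GPR references undeclared gene {gid!r}"
                        )
                    )
        if not rxn.mass_balance_exempt():
            issues.extend(_balance_issues(model, rxn, met_ids))

    return issues


def _balance_issues(
    model: MetabolicModel, rxn: Reaction, met_ids: set[str]
) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []
    participants = [
        model.metabolite(mid) for mid in rxn.stoichiometry if mid in met_ids
    ]
    if len(participants) != len(rxn.stoichiometry):
        return issues  # dangling references already reported

    compositions = [m.elements() for m in participants]
    if all(c is not None for c in compositions):
        net: dict[str, float] = {}
        for met, comp in zip(participants, compositions):
            coeff = rxn.stoichiometry[met.id]
            for element, count in comp.items():  # type: ignore[union-attr]
                net[element] = net.get(element, 0.0) + coeff * count
        unbalanced = {e: n for e, n in net.items() if abs(n) > 1e-9}
        if unbalanced:
            detail = ", ".join(f"{e}: {n:+g}" for e, n in sorted(unbalanced.items()))
            issues.append(
                ValidationIssue("error", rxn.id, f"mass imbalance ({detail})")
            )

    charges = [m.charge for m in participants]
    if all(c is not None for c in charges):
        net_charge = sum(
            rxn.stoichiometry[m.id] * m.charge for m in participants  # type: ignore[operator]
        )
        if abs(net_charge) > 1e-9:
            issues.append(
                ValidationIssue("error", rxn.id, f"charge imbalance ({net_charge:+g})")
            )
    return issues
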