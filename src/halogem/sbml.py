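"""SBML Level 3 (FBC) reading and writing.

Files are read and written through libSBML with the flux-balance
constraints (fbc) package: flux bounds arrive as referenced constant
parameters, gene associations as ``fbc:geneProductAssociation`` trees and
the objective as the active ``fbc:objective``.  Plain and
gzip-compressed input are both accepted.  The BiGG-style entity prefixes
(``M_``, ``R_``, ``G_``) are stripped on read and re-added on write, so
models interoperate with the wider COBRA ecosystem.

Whatever bound encoding a file uses (±1000 or ±infinity) is preserved
verbatim; bounds are only defaulted when a file omits them entirely.
"""

from __future__ import annotations

import gzip
import math
import os

import libsbml
import pandas as pd

from .gpr import BoolOp, GeneRef, GPRExpression
from .model import (
    DEFAULT_UPPER,
    Gene,
    MetabolicModel,
    Metabolite,
    Reaction,
    validate_model,
)

__all__ = ["read_sbml", "write_sbml", "summary_table", "write_summary_tsv"]

_FLUX_UNIT = "mmol_per_gDW_per_hr"


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _sbo_string(node) -> str | None:
    term = node.getSBOTerm()
    return None if term < 0 else f"SBO:{term:07d}"


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_sbml(path: str | os.PathLike) -> MetabolicModel:
    """Read an SBML L3/FBC file (plain or ``.gz``) into a model.

    Raises ``FileNotFoundError`` for a missing file, ``ValueError``
    naming the line for malformed XML, and ``ValueError`` listing the
    offending identifiers when a reaction references an undeclared
    species or gene product.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getModel() is None and _looks_gzipped(path):
        with gzip.open(path, "rt") as fh:
            doc = libsbml.readSBMLFromString(fh.read())
    _raise_on_xml_errors(doc, path)
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"{path}: no SBML model element found")
    return _convert(sbml_model, path)


def _looks_gzipped(path: str) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _raise_on_xml_errors(doc, path: str) -> None:
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ValueError(
                f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
            )


def _convert(sbml_model, path: str) -> MetabolicModel:
    model = MetabolicModel(
        id=sbml_model.getId() or "model", name=sbml_model.getName() or ""
    )
    for i in range(sbml_model.getNumCompartments()):
        model.compartments.add(sbml_model.getCompartment(i).getId())

    parameters = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        charge = None
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = fbc_sp.getChemicalFormula()
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        met_id = _strip("M_", sp.getId())
        compartment = sp.getCompartment() or _compartment_hint(met_id)
        model.metabolites.append(
            Metabolite(
                id=met_id,
                name=sp.getName() or "",
                compartment=compartment,
                formula=formula,
                charge=charge,
            )
        )

    fbc_model = sbml_model.getPlugin("fbc")
    gene_ids: set[str] = set()
    if fbc_model is not None:
        for i in range(fbc_model.getNumGeneProducts()):
            gp = fbc_model.getGeneProduct(i)
            gid = _strip("G_", gp.getId())
            gene_ids.add(gid)
            model.genes.append(Gene(id=gid, name=gp.getName() or gp.getLabel() or None))

    objective_coeffs: dict[str, float] = {}
    if fbc_model is not None and fbc_model.getActiveObjective() is not None:
        objective = fbc_model.getActiveObjective()
        sense = objective.getType()  # "maximize" / "minimize"
        sign = -1.0 if sense == "minimize" else 1.0
        for i in range(objective.getNumFluxObjectives()):
            fo = objective.getFluxObjective(i)
            objective_coeffs[_strip("R_", fo.getReaction())] = sign * fo.getCoefficient()

    met_ids = {m.id for m in model.metabolites}
    bad_species: list[str] = []
    bad_genes: list[str] = []

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = _strip("R_", rxn.getId())
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            mid = _strip("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            mid = _strip("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        for mid in stoich:
            if mid not in met_ids:
                bad_species.append(f"{rid}->{mid}")

        lower, upper = _reaction_bounds(rxn, parameters)
        gpr = _read_association(rxn, gene_ids, bad_genes, rid)
        model.reactions.append(
            Reaction(
                id=rid,
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
                gpr=gpr,
                objective_coefficient=objective_coeffs.get(rid, 0.0),
                sbo_term=_sbo_string(rxn),
            )
        )

    if bad_species or bad_genes:
        parts = []
        if bad_species:
            parts.append(f"undeclared species: {', '.join(sorted(bad_species))}")
        if bad_genes:
            parts.append(f"undeclared gene products: {', '.join(sorted(bad_genes))}")
        raise ValueError(f"{path}: validation failed; " + "; ".join(parts))
    return model


def _compartment_hint(met_id: str) -> str:
    for suffix, comp in (("_c", "c"), ("_p", "p"), ("_e", "e")):
        if met_id.endswith(suffix):
            return comp
    return "c"


def _reaction_bounds(rxn, parameters: dict[str, float]) -> tuple[float, float]:
    fbc_rxn = rxn.getPlugin("fbc")
    lower = upper = None
    if fbc_rxn is not None:
        if fbc_rxn.isSetLowerFluxBound():
            lower = parameters.get(fbc_rxn.getLowerFluxBound())
        if fbc_rxn.isSetUpperFluxBound():
            upper = parameters.get(fbc_rxn.getUpperFluxBound())
    reversible = rxn.getReversible()
    if lower is None:
        lower = -DEFAULT_UPPER if reversible else 0.0
    if upper is None:
        upper = DEFAULT_UPPER
    return float(lower), float(upper)


def _read_association(rxn, gene_ids, bad_genes: list[str], rid: str) -> GPRExpression | None:
    fbc_rxn = rxn.getPlugin("fbc")
    if fbc_rxn is None or fbc_rxn.getGeneProductAssociation() is None:
        return None
    assoc = fbc_rxn.getGeneProductAssociation().getAssociation()
    if assoc is None:
        return None
    expr = _assoc_to_expr(assoc)
    if expr is not None:
        for gid in sorted(expr.genes()):
            if gid not in gene_ids:
                bad_genes.append(f"{rid}->{gid}")
    return expr


def _assoc_to_expr(assoc) -> GPRExpression | None:
    if isinstance(assoc, libsbml.GeneProductRef):
        return GeneRef(_strip("G_", assoc.getGeneProduct()))
    if isinstance(assoc, (libsbml.FbcAnd, libsbml.FbcOr)):
        op = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
        children = [
            _assoc_to_expr(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        children = [c for c in children if c is not None]
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        return BoolOp(op, children)
    return None


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: str | os.PathLike) -> None:
    """Serialize a model to SBML L3V1 with the fbc v2 package.

    The written file round-trips: reading it back yields a model equal
    to the input on identifiers, bounds, stoichiometries, GPR strings
    and objective coefficients.
    """
    errors = [i for i in validate_model(model) if i.severity == "error"]
    if errors:
        detail = "; ".join(f"{i.entity}: {i.message}" for i in errors[:5])
        raise ValueError(f"model {model.id!r} fails validation: {detail}")

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    if model.name:
        sbml_model.setName(model.name)
    fbc_model = sbml_model.getPlugin("fbc")
    fbc_model.setStrict(True)

    unit_def = sbml_model.createUnitDefinition()
    unit_def.setId(_FLUX_UNIT)
    for kind, exponent, scale, multiplier in (
        (libsbml.UNIT_KIND_MOLE, 1, -3, 1.0),
        (libsbml.UNIT_KIND_GRAM, -1, 0, 1.0),
        (libsbml.UNIT_KIND_SECOND, -1, 0, 3600.0),
    ):
        unit = unit_def.createUnit()
        unit.setKind(kind)
        unit.setExponent(exponent)
        unit.setScale(scale)
        unit.setMultiplier(multiplier)

    compartments = sorted(model.compartments) or sorted(
        {m.compartment for m in model.metabolites}
    )
    for comp_id in compartments:
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(f"M_{met.id}")
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setInitialConcentration(0.0)
        fbc_sp = sp.getPlugin("fbc")
        if met.formula:
            fbc_sp.setChemicalFormula(met.formula)
        if met.charge is not None:
            fbc_sp.setCharge(int(met.charge))

    for gene in model.genes:
        gp = fbc_model.createGeneProduct()
        gp.setId(f"G_{gene.id}")
        gp.setLabel(gene.name or gene.id)
        if gene.name:
            gp.setName(gene.name)

    # bound parameters: one shared constant parameter per distinct value,
    # numbered in first-encounter order so serialization is deterministic
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            par.setUnits(_FLUX_UNIT)
            if math.isinf(value):
                par.setValue(float("inf") if value > 0 else float("-inf"))
            bound_params[value] = pid
        return bound_params[value]

    objective = fbc_model.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fbc_model.setActiveObjectiveId("obj")

    for rxn in model.reactions:
        sbml_rxn = sbml_model.createReaction()
        sbml_rxn.setId(f"R_{rxn.id}")
        if rxn.name:
            sbml_rxn.setName(rxn.name)
        sbml_rxn.setFast(False)
        sbml_rxn.setReversible(rxn.lower_bound < 0)
        if rxn.sbo_term:
            sbml_rxn.setSBOTerm(rxn.sbo_term)
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = sbml_rxn.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = sbml_rxn.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(f"M_{met_id}")
            ref.setConstant(True)
        fbc_rxn = sbml_rxn.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(bound_param(rxn.lower_bound))
        fbc_rxn.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = fbc_rxn.createGeneProductAssociation()
            status = gpa.setAssociation(_expr_to_assoc_string(rxn.gpr), True, False)
            if status != libsbml.LIBSBML_OPERATION_SUCCESS:
                raise ValueError(
                    f"could not encode GPR {rxn.gpr.to_string()!r} of reaction {rxn.id!r}"
                )
        if rxn.objective_coefficient != 0.0:
            fo = objective.createFluxObjective()
            fo.setReaction(f"R_{rxn.id}")
            fo.setCoefficient(rxn.objective_coefficient)

    status = libsbml.writeSBMLToFile(doc, os.fspath(path))
    if status != 1:
        raise IOError(f"could not write SBML to {path!r}")


def _expr_to_assoc_string(expr: GPRExpression) -> str:
    if isinstance(expr, GeneRef):
        return f"G_{expr.gene}"
    assert isinstance(expr, BoolOp)
    parts = [f"({_expr_to_assoc_string(c)})" for c in expr.children]
    return f" {expr.op} ".join(parts)


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def summary_table(model: MetabolicModel) -> pd.DataFrame:
    """One row per reaction: id, bounds, GPR string, subsystem."""
    rows = [
        {
            "reaction": r.id,
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "gpr": r.gpr.to_string() if r.gpr is not None else "",
            "subsystem": r.subsystem,
        }
        for r in model.reactions
    ]
    return pd.DataFrame(rows, columns=["reaction", "lower_bound", "upper_bound", "gpr", "subsystem"])


def write_summary_tsv(model: MetabolicModel, path: str | os.PathLike) -> None:
    summary_table(model).to_csv(path, sep="\t", index=False)
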