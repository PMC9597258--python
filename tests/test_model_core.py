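"""Model container, SBML round-tripping and structural validation."""

import gzip
import xml.etree.ElementTree as ET

import pytest

from halogem import (
    Gene,
    MetabolicModel,
    Metabolite,
    Reaction,
    make_chain,
    make_chain_with_nitrogen,
    make_production_branch,
    make_random_network,
    parse_formula,
    read_sbml,
    summary_table,
    validate_model,
    write_sbml,
)


def models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    if [m.id for m in a.metabolites] != [m.id for m in b.metabolites]:
        return False
    if [g.id for g in a.genes] != [g.id for g in b.genes]:
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if ra.id != rb.id or ra.stoichiometry != rb.stoichiometry:
            return False
        if abs(ra.lower_bound - rb.lower_bound) > 1e-9:
            return False
        if abs(ra.upper_bound - rb.upper_bound) > 1e-9:
            return False
        if abs(ra.objective_coefficient - rb.objective_coefficient) > 1e-9:
            return False
        gpr_a = ra.gpr.to_string() if ra.gpr else None
        gpr_b = rb.gpr.to_string() if rb.gpr else None
        if gpr_a != gpr_b:
            return False
    return len(a.reactions) == len(b.reactions)


@pytest.mark.parametrize(
    "factory",
    [
        lambda: make_chain(1, 10.0),
        lambda: make_chain(5, 3.5),
        lambda: make_chain_with_nitrogen(10.0, 2),
        lambda: make_production_branch(10.0, 1.0, 0.5),
        lambda: make_random_network(7),
        lambda: make_random_network(23, n_metabolites=10, n_reactions=16),
    ],
)
def test_sbml_round_trip(tmp_path, factory):
    """write -> read preserves ids, bounds, stoichiometry, GPRs, objective."""
    model = factory()
    path = tmp_path / "model.xml"
    write_sbml(model, path)
    assert models_equal(model, read_sbml(path))


def test_round_trip_preserves_encoded_bound_magnitudes(tmp_path, chain3):
    """Bounds written as +/-1000 come back exactly, not normalized."""
    path = tmp_path / "m.xml"
    write_sbml(chain3, path)
    back = read_sbml(path)
    assert back.reaction("EX_A_e").lower_bound == -10.0
    assert back.reaction("EX_A_e").upper_bound == 1000.0
    assert back.reaction("T_A").upper_bound == 1000.0


def test_read_counts_match_independent_xml_scan(tmp_path):
    """Entity counts agree with a plain ElementTree scan of the file."""
    model = make_random_network(11, n_metabolites=9, n_reactions=14)
    path = tmp_path / "m.xml"
    write_sbml(model, path)
    tree = ET.parse(path)
    ns = {
        "sbml": "http://www.sbml.org/sbml/level3/version1/core",
        "fbc": "http://www.sbml.org/sbml/level3/version1/fbc/version2",
    }
    species = tree.findall(".//sbml:listOfSpecies/sbml:species", ns)
    reactions = tree.findall(".//sbml:listOfReactions/sbml:reaction", ns)
    gene_products = tree.findall(".//fbc:listOfGeneProducts/fbc:geneProduct", ns)
    loaded = read_sbml(path)
    assert len(loaded.metabolites) == len(species)
    assert len(loaded.reactions) == len(reactions)
    assert len(loaded.genes) == len(gene_products)


def test_read_gzip_compressed_sbml(tmp_path, chain3):
    plain = tmp_path / "m.xml"
    write_sbml(chain3, plain)
    gz = tmp_path / "m.xml.gz"
    gz.write_bytes(gzip.compress(plain.read_bytes()))
    assert models_equal(chain3, read_sbml(gz))


def test_read_missing_file_raises_io_error():
    with pytest.raises(FileNotFoundError):
        read_sbml("/nonexistent/model.xml")


def test_read_malformed_xml_names_line(tmp_path):
    path = tmp_path / "bad.xml"
    path.write_text("<?xml version='1.0'?>\n<sbml><model></sbml>\n")
    with pytest.raises(ValueError, match="line"):
        read_sbml(path)


def test_read_reaction_with_undeclared_species_names_the_id(tmp_path, chain3_file):
    text = chain3_file.read_text().replace(
        'species="M_A_c"', 'species="M_ghost_c"', 1
    )
    bad = chain3_file.parent / "bad_species.xml"
    bad.write_text(text)
    with pytest.raises(ValueError, match="ghost_c"):
        read_sbml(bad)


def test_model_without_objective_still_round_trips(tmp_path, chain3):
    for rxn in chain3.reactions:
        rxn.objective_coefficient = 0.0
    path = tmp_path / "noobj.xml"
    write_sbml(chain3, path)
    back = read_sbml(path)
    assert all(r.objective_coefficient == 0.0 for r in back.reactions)


def test_write_rejects_invalid_model(tmp_path, chain3):
    chain3.reaction("R1").lower_bound = 5.0
    chain3.reaction("R1").upper_bound = -5.0
    with pytest.raises(ValueError, match="validation"):
        write_sbml(chain3, tmp_path / "x.xml")


# -- validation -----------------------------------------------------------


def test_clean_fixtures_validate_without_issues(chain3, chain3n, toyprod, cntoy):
    for model in (chain3, chain3n, toyprod, cntoy):
        assert validate_model(model) == []


def test_mass_imbalance_detected_on_internal_reaction():
    model = MetabolicModel(
        id="imbalanced",
        compartments={"c"},
        metabolites=[
            Metabolite("A_c", compartment="c", formula="C6H12O6"),
            Metabolite("B_c", compartment="c", formula="C6H12O6"),
        ],
        reactions=[
            Reaction(id="BAD", stoichiometry={"A_c": -1.0, "B_c": 2.0}, lower_bound=0.0)
        ],
    )
    issues = validate_model(model)
    assert any("mass imbalance" in i.message and "C: +6" in i.message for i in issues)


def test_exchange_reactions_exempt_from_mass_balance():
    model = MetabolicModel(
        id="exch",
        compartments={"e"},
        metabolites=[Metabolite("A_e", compartment="e", formula="C6H12O6")],
        reactions=[
            Reaction(
                id="EX_A_e",
                stoichiometry={"A_e": -1.0},
                sbo_term="SBO:0000627",
            )
        ],
    )
    assert validate_model(model) == []


def test_charge_imbalance_detected():
    model = MetabolicModel(
        id="chg",
        compartments={"c"},
        metabolites=[
            Metabolite("A_c", compartment="c", charge=0),
            Metabolite("B_c", compartment="c", charge=1),
        ],
        reactions=[
            Reaction(id="BAD", stoichiometry={"A_c": -1.0, "B_c": 1.0}, lower_bound=0.0)
        ],
    )
    assert any("charge imbalance" in i.message for i in validate_model(model))


def test_bound_violation_and_dangling_references_reported(chain3):
    chain3.reaction("R1").lower_bound = 7.0
    chain3.reaction("R1").upper_bound = -7.0
    chain3.reaction("T_A").stoichiometry["missing_c"] = 1.0
    chain3.genes = [g for g in chain3.genes if g.id != "g1"]
    messages = [i.message for i in validate_model(chain3)]
    assert any("lower bound" in m for m in messages)
    assert any("missing_c" in m for m in messages)
    assert any("g1" in m for m in messages)


def test_duplicate_ids_reported(chain3):
    chain3.metabolites.append(Metabolite("A_c", compartment="c"))
    assert any(
        i.message == "duplicate metabolite id" and i.entity == "A_c"
        for i in validate_model(chain3)
    )


# -- misc -----------------------------------------------------------------


@pytest.mark.parametrize(
    "formula,expected",
    [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("CO2", {"C": 1, "O": 2}),
        ("N", {"N": 1}),
        ("C4H6NO4Se", {"C": 4, "H": 6, "N": 1, "O": 4, "Se": 1}),
    ],
)
def test_formula_parsing(formula, expected):
    assert parse_formula(formula) == expected


def test_formula_parsing_rejects_garbage():
    with pytest.raises(ValueError):
        parse_formula("C6(H2O)6")


def test_summary_table_lists_every_reaction(chain3):
    table = summary_table(chain3)
    assert list(table["reaction"]) == [r.id for r in chain3.reactions]
    assert table.loc[table.reaction == "R1", "gpr"].item() == "g2 or g3"
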