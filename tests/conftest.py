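import pytest

from halogem import (
    Medium,
    make_carbon_nitrogen,
    make_chain,
    make_chain_with_nitrogen,
    make_production_branch,
    write_sbml,
)


@pytest.fixture
def chain3():
    """Linear toy: EX_A_e -> T_A (g1) -> R1 (g2 or g3) -> BIOMASS, optimum 10."""
    return make_chain(1, 10.0)


@pytest.fixture
def chain3_medium():
    return Medium({"EX_A_e": 10.0})


@pytest.fixture
def chain3_file(tmp_path, chain3):
    path = tmp_path / "chain3.xml"
    write_sbml(chain3, path)
    return path


@pytest.fixture
def chain3n():
    """Chain plus one nitrogen source and a dispensable substrate."""
    return make_chain_with_nitrogen(10.0, n_nitrogen_sources=1)


@pytest.fixture
def toyprod():
    """Branched toy: carbon splits between biomass and a product demand."""
    return make_production_branch(10.0, 1.0, 1.0)


@pytest.fixture
def cntoy():
    """Two-resource toy: biomass needs C and N 1:1, product needs C only."""
    return make_carbon_nitrogen(10.0, 4.0)
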