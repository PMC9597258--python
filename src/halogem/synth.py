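"""Synthetic toy metabolic networks with analytically known solutions.

Each generator builds a small, fully valid model whose FBA optimum,
essential-gene set or production envelope is known in closed form, so
every pipeline stage can be verified without any external model file:

``make_chain``
    linear uptake chain; growth equals the sole uptake bound exactly.
``make_chain_with_nitrogen``
    the chain plus one or more interchangeable nitrogen sources and a
    dispensable substrate, exercising minimal-medium logic.
``make_production_branch``
    carbon splits between biomass and a product demand; the production
    envelope is the exact line
    ``product_max = yield_product * (uptake - biomass / yield_biomass)``.
``make_carbon_nitrogen``
    biomass consumes C and N 1:1 while the product consumes C only, so
    growth = min(uptake_C, uptake_N) and product-at-optimum =
    uptake_C - growth (the two-resource phase-plane toy).
``make_random_network``
    seeded sparse random network with a hand-planted feasible path to
    biomass, for oracle-equivalence testing; identical seed and
    parameters reproduce the model byte-for-byte.
"""

from __future__ import annotations

import numpy as np

from .gpr import parse_gpr
from .model import (
    DEFAULT_UPPER,
    SBO_BIOMASS,
    SBO_EXCHANGE,
    Gene,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = [
    "make_chain",
    "make_chain_with_nitrogen",
    "make_production_branch",
    "make_carbon_nitrogen",
    "make_random_network",
]


def _exchange(met_id: str, uptake: float) -> Reaction:
    return Reaction(
        id=f"EX_{met_id}",
        name=f"{met_id} exchange",
        stoichiometry={met_id: -1.0},
        lower_bound=-uptake,
        upper_bound=DEFAULT_UPPER,
        sbo_term=SBO_EXCHANGE,
    )


def make_chain(n: int = 1, uptake: float = 10.0) -> MetabolicModel:
    """Linear chain: exchange -> transport -> n conversions -> biomass.

    ``make_chain(1, 10)`` is the canonical CHAIN3 fixture: metabolites
    A_e, A_c, B_c; reactions EX_A, T_A (GPR ``g1``), R1 (GPR
    ``g2 or g3``) and BIOMASS; FBA optimum = uptake.  Gene g1 is the
    sole essential gene (single transporter); g2/g3 are isozymes.
    """
    if n < 1:
        raise ValueError("chain length n must be >= 1")
    if uptake < 0:
        raise ValueError("uptake must be >= 0")
    model = MetabolicModel(id=f"chain{n}", compartments={"c", "e"})
    model.genes = [Gene("g1"), Gene("g2"), Gene("g3")]
    model.metabolites.append(Metabolite("A_e", compartment="e", formula="C6H12O6"))
    model.metabolites.append(Metabolite("A_c", compartment="c", formula="C6H12O6"))
    internal = ["A_c"]
    for i in range(1, n + 1):
        mid = f"B{i}_c" if n > 1 else "B_c"
        model.metabolites.append(Metabolite(mid, compartment="c", formula="C6H12O6"))
        internal.append(mid)

    model.reactions.append(_exchange("A_e", uptake))
    model.reactions.append(
        Reaction(
            id="T_A",
            name="A transport",
            stoichiometry={"A_e": -1.0, "A_c": 1.0},
            lower_bound=0.0,
            gpr=parse_gpr("g1"),
        )
    )
    for i in range(n):
        model.reactions.append(
            Reaction(
                id=f"R{i + 1}",
                name=f"conversion {i + 1}",
                stoichiometry={internal[i]: -1.0, internal[i + 1]: 1.0},
                lower_bound=0.0,
                gpr=parse_gpr("g2 or g3") if i == 0 else None,
            )
        )
    model.reactions.append(
        Reaction(
            id="BIOMASS",
            name="biomass",
            stoichiometry={internal[-1]: -1.0},
            lower_bound=0.0,
            objective_coefficient=1.0,
            sbo_term=SBO_BIOMASS,
        )
    )
    return model


def make_chain_with_nitrogen(
    uptake: float = 10.0,
    n_nitrogen_sources: int = 1,
    with_dispensable: bool = True,
) -> MetabolicModel:
    """CHAIN3 extended with nitrogen requirement(s) and a spare substrate.

    Biomass consumes B_c and N_c 1:1.  With one nitrogen source the
    minimal medium is exactly {EX_A, EX_N1}.  With two or more, the
    sources are interchangeable: each tests non-essential alone yet at
    least one is needed jointly -- the degenerate case the greedy
    joint-sufficiency repair exists for.  The dispensable substrate X
    can also feed the chain but is never required while A is present.
    """
    if n_nitrogen_sources < 1:
        raise ValueError("need at least one nitrogen source")
    model = make_chain(1, uptake)
    model.id = "chain3n"
    model.metabolites.append(Metabolite("N_c", compartment="c", formula="N"))
    biomass = model.reaction("BIOMASS")
    biomass.stoichiometry["N_c"] = -1.0

    for i in range(1, n_nitrogen_sources + 1):
        ne = f"N{i}_e"
        model.metabolites.append(Metabolite(ne, compartment="e", formula="N"))
        model.reactions.insert(
            len(model.reactions) - 1, _exchange(ne, uptake)
        )
        model.reactions.insert(
            len(model.reactions) - 1,
            Reaction(
                id=f"T_N{i}",
                name=f"nitrogen transport {i}",
                stoichiometry={ne: -1.0, "N_c": 1.0},
                lower_bound=0.0,
            ),
        )

    if with_dispensable:
        model.metabolites.append(Metabolite("X_e", compartment="e", formula="C6H12O6"))
        model.reactions.insert(
            len(model.reactions) - 1, _exchange("X_e", uptake)
        )
        model.reactions.insert(
            len(model.reactions) - 1,
            Reaction(
                id="T_X",
                name="X transport feeding the chain",
                stoichiometry={"X_e": -1.0, "A_c": 1.0},
                lower_bound=0.0,
            ),
        )
    return model


def make_production_branch(
    uptake: float = 10.0,
    yield_biomass: float = 1.0,
    yield_product: float = 1.0,
) -> MetabolicModel:
    """TOYPROD: carbon splits between biomass and a product demand.

    Closed form: ``product_max(mu) = yield_product * (uptake -
    mu / yield_biomass)`` for biomass flux mu in [0, yield_biomass *
    uptake].
    """
    if uptake < 0:
        raise ValueError("uptake must be >= 0")
    if yield_biomass <= 0 or yield_product <= 0:
        raise ValueError("yields must be > 0")
    model = MetabolicModel(id="toyprod", compartments={"c", "e"})
    model.genes = [Gene("g1"), Gene("g2")]
    model.metabolites = [
        Metabolite("A_e", compartment="e", formula="C6H12O6"),
        Metabolite("A_c", compartment="c", formula="C6H12O6"),
        # product composition left unspecified: the synthesis yield is a free
        # parameter, so no fixed formula could stay elementally balanced
        Metabolite("P_c", compartment="c"),
    ]
    model.reactions = [
        _exchange("A_e", uptake),
        Reaction(
            id="T_A",
            name="A transport",
            stoichiometry={"A_e": -1.0, "A_c": 1.0},
            lower_bound=0.0,
            gpr=parse_gpr("g1"),
        ),
        Reaction(
            id="PSYN",
            name="product synthesis",
            stoichiometry={"A_c": -1.0, "P_c": yield_product},
            lower_bound=0.0,
            gpr=parse_gpr("g2"),
        ),
        Reaction(
            id="DM_P_c",
            name="product demand",
            stoichiometry={"P_c": -1.0},
            lower_bound=0.0,
        ),
        Reaction(
            id="BIOMASS",
            name="biomass",
            stoichiometry={"A_c": -1.0 / yield_biomass},
            lower_bound=0.0,
            objective_coefficient=1.0,
            sbo_term=SBO_BIOMASS,
        ),
    ]
    return model


def make_carbon_nitrogen(
    uptake_c: float = 10.0, uptake_n: float = 10.0
) -> MetabolicModel:
    """CN-TOY: biomass needs C and N 1:1; the product needs C only.

    Growth optimum = min(uptake_c, uptake_n); maximal product flux at
    that optimum = uptake_c - growth.
    """
    if uptake_c < 0 or uptake_n < 0:
        raise ValueError("uptakes must be >= 0")
    model = MetabolicModel(id="cntoy", compartments={"c", "e"})
    model.metabolites = [
        Metabolite("C_e", compartment="e", formula="C6H12O6"),
        Metabolite("C_c", compartment="c", formula="C6H12O6"),
        Metabolite("N_e", compartment="e", formula="N"),
        Metabolite("N_c", compartment="c", formula="N"),
        Metabolite("P_c", compartment="c"),
    ]
    model.reactions = [
        _exchange("C_e", uptake_c),
        _exchange("N_e", uptake_n),
        Reaction(
            id="T_C",
            stoichiometry={"C_e": -1.0, "C_c": 1.0},
            lower_bound=0.0,
        ),
        Reaction(
            id="T_N",
            stoichiometry={"N_e": -1.0, "N_c": 1.0},
            lower_bound=0.0,
        ),
        Reaction(
            id="PSYN",
            name="product synthesis",
            stoichiometry={"C_c": -1.0, "P_c": 1.0},
            lower_bound=0.0,
        ),
        Reaction(
            id="DM_P_c",
            stoichiometry={"P_c": -1.0},
            lower_bound=0.0,
        ),
        Reaction(
            id="BIOMASS",
            stoichiometry={"C_c": -1.0, "N_c": -1.0},
            lower_bound=0.0,
            objective_coefficient=1.0,
            sbo_term=SBO_BIOMASS,
        ),
    ]
    return model


def make_random_network(
    seed: int,
    n_metabolites: int = 8,
    n_reactions: int = 12,
    n_genes: int = 6,
    uptake: float = 10.0,
) -> MetabolicModel:
    """Seeded sparse random network with a planted feasible path.

    Construction: a substrate exchange, a transporter and a short
    conversion chain into the biomass precursor guarantee a nonzero FBA
    optimum (no rejection sampling); extra reactions draw random sparse
    stoichiometry with coefficients in {-2, -1, 1, 2} over the internal
    metabolites, random reversibility and random one- or two-gene GPR
    rules (``a``, ``a and b``, or ``a or b``).  Small enough (<= 12
    metabolites, <= 20 reactions) that brute-force LP oracles stay
    cheap.  Everything is drawn from one ``numpy`` generator, so the
    same seed and sizes reproduce the model exactly.
    """
    if not 3 <= n_metabolites <= 12:
        raise ValueError("n_metabolites must be in [3, 12]")
    if not 4 <= n_reactions <= 20:
        raise ValueError("n_reactions must be in [4, 20]")
    if not 1 <= n_genes <= 8:
        raise ValueError("n_genes must be in [1, 8]")
    rng = np.random.default_rng(seed)

    model = MetabolicModel(id=f"rand{seed}", compartments={"c", "e"})
    model.genes = [Gene(f"g{i + 1}") for i in range(n_genes)]
    model.metabolites.append(Metabolite("s_e", compartment="e"))
    internal = [f"m{i}_c" for i in range(n_metabolites - 1)]
    for mid in internal:
        model.metabolites.append(Metabolite(mid, compartment="c"))

    def random_gpr():
        roll = rng.integers(0, 4)
        if roll == 0 or n_genes == 1:
            return None
        a, b = rng.choice(n_genes, size=2, replace=False) + 1
        if roll == 1:
            return parse_gpr(f"g{a}")
        op = "and" if roll == 2 else "or"
        return parse_gpr(f"g{a} {op} g{b}")

    # planted path: EX_s -> T_s -> chain over the first few internals -> biomass
    path_len = min(3, len(internal))
    model.reactions.append(_exchange("s_e", uptake))
    model.reactions.append(
        Reaction(
            id="T_s",
            stoichiometry={"s_e": -1.0, internal[0]: 1.0},
            lower_bound=0.0,
            gpr=random_gpr(),
        )
    )
    for i in range(path_len - 1):
        model.reactions.append(
            Reaction(
                id=f"P{i + 1}",
                stoichiometry={internal[i]: -1.0, internal[i + 1]: 1.0},
                lower_bound=0.0,
                gpr=random_gpr(),
            )
        )
    precursor = internal[path_len - 1]

    n_extra = n_reactions - (2 + (path_len - 1) + 1)
    for k in range(max(0, n_extra)):
        n_part = int(rng.integers(2, min(4, len(internal)) + 1))
        members = rng.choice(len(internal), size=n_part, replace=False)
        coeffs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=n_part)
        if all(c > 0 for c in coeffs):
            coeffs[0] = -1.0
        if all(c < 0 for c in coeffs):
            coeffs[-1] = 1.0
        reversible = bool(rng.integers(0, 2))
        model.reactions.append(
            Reaction(
                id=f"X{k + 1}",
                stoichiometry={
                    internal[int(m)]: float(c) for m, c in zip(members, coeffs)
                },
                lower_bound=-DEFAULT_UPPER if reversible else 0.0,
                gpr=random_gpr(),
            )
        )

    model.reactions.append(
        Reaction(
            id="BIOMASS",
            stoichiometry={precursor: -1.0},
            lower_bound=0.0,
            objective_coefficient=1.0,
            sbo_term=SBO_BIOMASS,
        )
    )
    return model
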