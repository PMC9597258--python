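"""Media, minimal-medium reduction, screens, demands and envelopes."""

import math

import numpy as np
import pytest

from halogem import (
    Medium,
    Metabolite,
    Reaction,
    add_demand_reaction,
    anaerobic_growth_test,
    build_system,
    carbon_secretion_check,
    carbon_source_screen,
    determine_minimal_medium,
    grows_on,
    make_chain,
    make_chain_with_nitrogen,
    make_production_branch,
    max_production,
    phase_plane,
    production_envelope,
    set_medium,
    solve_fba,
    validate_model,
)

TOL = 1e-6


# -- media ----------------------------------------------------------------


def test_set_medium_opens_listed_and_closes_other_exchanges(chain3n):
    overrides = set_medium(chain3n, Medium({"EX_A_e": 10.0}))
    assert overrides["EX_A_e"] == (-10.0, 1000.0)
    assert overrides["EX_N1_e"][0] == 0.0  # uptake closed
    assert overrides["EX_N1_e"][1] == 1000.0  # secretion untouched


def test_empty_medium_means_no_growth(chain3):
    growth, grows = grows_on(chain3, Medium({}))
    assert growth == pytest.approx(0.0, abs=TOL)
    assert not grows


def test_medium_naming_internal_reaction_is_contract_error(chain3):
    with pytest.raises(ValueError, match="non-exchange"):
        set_medium(chain3, Medium({"R1": 10.0}))


def test_medium_rejects_negative_rates():
    with pytest.raises(ValueError, match=">= 0"):
        Medium({"EX_A_e": -1.0})


def test_screen_monotonicity_in_uptake(chain3):
    growths = [grows_on(chain3, Medium({"EX_A_e": u}))[0] for u in (0, 2, 5, 10)]
    assert all(b >= a - TOL for a, b in zip(growths, growths[1:]))


# -- minimal medium -------------------------------------------------------


def test_minimal_medium_keeps_carbon_and_nitrogen_only(chain3n):
    full = Medium({"EX_A_e": 10, "EX_N1_e": 10, "EX_X_e": 10})
    result = determine_minimal_medium(chain3n, full, "EX_A_e")
    assert set(result.medium.uptake_limits) == {"EX_A_e", "EX_N1_e"}
    audit = {a.component: a for a in result.audit}
    assert audit["EX_N1_e"].essential
    assert not audit["EX_X_e"].essential
    assert not audit["EX_X_e"].restored
    assert result.secreted_carbon == []


def test_minimal_medium_carbon_only_chain(chain3):
    result = determine_minimal_medium(chain3, Medium({"EX_A_e": 10}), "EX_A_e")
    assert set(result.medium.uptake_limits) == {"EX_A_e"}


def test_interchangeable_nutrients_trigger_flagged_greedy_repair():
    model = make_chain_with_nitrogen(10.0, n_nitrogen_sources=2)
    full = Medium({"EX_A_e": 10, "EX_N1_e": 10, "EX_N2_e": 10, "EX_X_e": 10})
    result = determine_minimal_medium(model, full, "EX_A_e")
    audit = {a.component: a for a in result.audit}
    # each nitrogen source tests non-essential alone ...
    assert not audit["EX_N1_e"].essential
    assert not audit["EX_N2_e"].essential
    # ... yet one must be restored jointly, and the restoration is flagged
    restored = [a.component for a in result.audit if a.restored]
    assert restored == ["EX_N1_e"]
    assert set(result.medium.uptake_limits) == {"EX_A_e", "EX_N1_e"}


def test_minimal_medium_soundness_reverified(chain3n):
    """Model grows on the minimal set; closing any essential part kills it."""
    full = Medium({"EX_A_e": 10, "EX_N1_e": 10, "EX_X_e": 10})
    result = determine_minimal_medium(chain3n, full, "EX_A_e")
    growth, grows = grows_on(chain3n, result.medium)
    assert grows and growth == pytest.approx(result.growth_on_minimal, abs=TOL)
    for a in result.audit:
        if a.essential:
            _, still_grows = grows_on(chain3n, result.medium.without(a.component))
            assert not still_grows


def test_minimal_medium_requires_growth_on_full(chain3):
    with pytest.raises(ValueError, match="does not grow"):
        determine_minimal_medium(chain3, Medium({"EX_A_e": 0.0}), "EX_A_e")


# -- carbon secretion -----------------------------------------------------


def secreting_model():
    """Chain variant forced to secrete its carbon product."""
    model = make_production_branch(10.0, 1.0, 1.0)
    model.metabolites.append(Metabolite("P_e", compartment="e", formula="C4H6O2"))
    model.reactions.insert(
        0,
        Reaction(
            id="EX_P_e",
            stoichiometry={"P_e": -1.0},
            lower_bound=0.0,
            sbo_term="SBO:0000627",
        ),
    )
    model.reactions.append(
        Reaction(id="T_P", stoichiometry={"P_c": -1.0, "P_e": 1.0}, lower_bound=0.0)
    )
    # force product formation: at least 4 units leave as product
    model.reaction("T_P").lower_bound = 4.0
    assert validate_model(model) == []
    return model


def test_biomass_only_sink_passes_secretion_check(chain3, chain3_medium):
    system = build_system(chain3).with_bounds(set_medium(chain3, chain3_medium))
    assert carbon_secretion_check(chain3, solve_fba(system)) == []


def test_forced_product_secretion_is_listed():
    model = secreting_model()
    medium = Medium({"EX_A_e": 10.0})
    system = build_system(model).with_bounds(set_medium(model, medium))
    offending = carbon_secretion_check(model, solve_fba(system))
    assert len(offending) == 1
    assert offending[0]["exchange"] == "EX_P_e"
    assert offending[0]["rate"] == pytest.approx(4.0, abs=TOL)
    assert offending[0]["status"] == "carbon-secretion"


def test_co2_secretion_is_exempt():
    model = make_chain(1, 10.0)
    model.metabolites.append(Metabolite("co2_e", compartment="e", formula="CO2"))
    model.reactions.append(
        Reaction(
            id="EX_co2_e",
            stoichiometry={"co2_e": -1.0},
            lower_bound=0.0,
            sbo_term="SBO:0000627",
        )
    )
    # synthetic solution secreting only CO2
    from halogem import FluxSolution

    solution = FluxSolution(
        status="optimal",
        objective_value=10.0,
        fluxes={"EX_co2_e": 5.0, "EX_A_e": -10.0},
    )
    assert carbon_secretion_check(model, solution) == []


def test_unknown_formula_secretion_is_flagged(toyprod):
    from halogem import FluxSolution

    toyprod.metabolites.append(Metabolite("mys_e", compartment="e"))
    toyprod.reactions.append(
        Reaction(
            id="EX_mys_e",
            stoichiometry={"mys_e": -1.0},
            lower_bound=0.0,
            sbo_term="SBO:0000627",
        )
    )
    solution = FluxSolution(status="optimal", objective_value=0.0, fluxes={"EX_mys_e": 1.0})
    offending = carbon_secretion_check(toyprod, solution)
    assert offending[0]["status"] == "unknown-formula"


# -- carbon screen and anaerobic test -------------------------------------


def test_carbon_screen_on_chain(chain3):
    result = carbon_source_screen(chain3, Medium({}), ["EX_A_e"], uptake=10.0)
    row = result.row("EX_A_e")
    assert row.grows and row.growth == pytest.approx(10.0, abs=TOL)


def test_carbon_screen_reports_absent_candidates(chain3):
    result = carbon_source_screen(chain3, Medium({}), ["EX_A_e", "EX_missing_e"])
    assert result.row("EX_missing_e").note == "not in model"
    assert not result.row("EX_missing_e").grows
    assert math.isnan(result.row("EX_missing_e").growth)


def test_carbon_screen_candidates_tested_one_at_a_time():
    """Opening candidate B must not leak into candidate A's condition."""
    model = make_chain_with_nitrogen(10.0, 1)  # X_e is an alternative carbon
    minimal = Medium({"EX_A_e": 10, "EX_N1_e": 10})
    result = carbon_source_screen(model, minimal, ["EX_A_e", "EX_X_e"], uptake=7.0)
    assert result.row("EX_A_e").growth == pytest.approx(7.0, abs=TOL)
    assert result.row("EX_X_e").growth == pytest.approx(7.0, abs=TOL)


def aerobic_model():
    """Chain whose biomass stoichiometrically requires oxygen."""
    model = make_chain(1, 10.0)
    model.metabolites.extend(
        [
            Metabolite("o2_e", compartment="e", formula="O2"),
            Metabolite("o2_c", compartment="c", formula="O2"),
        ]
    )
    model.reactions.insert(
        0,
        Reaction(
            id="EX_o2_e",
            stoichiometry={"o2_e": -1.0},
            lower_bound=-1000.0,
            sbo_term="SBO:0000627",
        ),
    )
    model.reactions.append(
        Reaction(id="O2t", stoichiometry={"o2_e": -1.0, "o2_c": 1.0}, lower_bound=0.0)
    )
    model.reaction("BIOMASS").stoichiometry["o2_c"] = -1.0
    return model


def test_oxygen_requiring_biomass_stops_growing_anaerobically():
    model = aerobic_model()
    medium = Medium({"EX_A_e": 10.0, "EX_o2_e": 1000.0})
    aerobic_growth, grows = grows_on(model, medium)
    assert grows and aerobic_growth == pytest.approx(10.0, abs=TOL)
    result = anaerobic_growth_test(model, medium, [])
    assert result.rows[0].condition == "anaerobic"
    assert not result.rows[0].grows


def test_anaerobic_acceptor_rows_and_missing_oxygen_error(chain3):
    model = aerobic_model()
    medium = Medium({"EX_A_e": 10.0, "EX_o2_e": 1000.0})
    result = anaerobic_growth_test(model, medium, ["EX_A_e", "EX_no3_e"])
    assert [r.condition for r in result.rows] == [
        "anaerobic",
        "anaerobic+EX_A_e",
        "anaerobic+EX_no3_e",
    ]
    assert result.row("anaerobic+EX_no3_e").note == "not in model"
    with pytest.raises(ValueError, match="oxygen"):
        anaerobic_growth_test(chain3, Medium({"EX_A_e": 10.0}), [])


# -- demand reactions and production --------------------------------------


def test_add_demand_reaction_construction(toyprod):
    rid = add_demand_reaction(toyprod, "A_c")
    assert rid == "DM_A_c"
    demand = toyprod.reaction(rid)
    assert demand.stoichiometry == {"A_c": -1.0}
    assert demand.lower_bound == 0.0
    assert demand.sbo_term == "SBO:0000628"
    assert validate_model(toyprod) == []


def test_add_demand_duplicate_and_unknown_are_errors(toyprod):
    with pytest.raises(ValueError, match="already present"):
        add_demand_reaction(toyprod, "P_c")  # DM_P_c exists
    with pytest.raises(KeyError):
        add_demand_reaction(toyprod, "nope_c")


def test_demand_addition_is_growth_neutral(chain3, chain3_medium):
    before, _ = grows_on(chain3, chain3_medium)
    add_demand_reaction(chain3, "A_c")
    after, _ = grows_on(chain3, chain3_medium)
    assert after == pytest.approx(before, abs=TOL)


@pytest.mark.parametrize(
    "yield_biomass,yield_product,expected",
    [(1.0, 1.0, 10.0), (1.0, 0.5, 5.0), (2.0, 1.0, 10.0)],
)
def test_max_production_at_zero_growth(yield_biomass, yield_product, expected):
    model = make_production_branch(10.0, yield_biomass, yield_product)
    solution = max_production(model, Medium({"EX_A_e": 10.0}), "DM_P_c", 0.0)
    assert solution.optimal
    assert solution.objective_value == pytest.approx(expected, abs=TOL)


def test_max_production_at_full_growth_is_zero(toyprod):
    solution = max_production(toyprod, Medium({"EX_A_e": 10.0}), "DM_P_c", 1.0)
    assert solution.objective_value == pytest.approx(0.0, abs=TOL)


def test_max_production_requires_growing_wildtype(toyprod):
    with pytest.raises(ValueError, match="wildtype"):
        max_production(toyprod, Medium({}), "DM_P_c", 0.5)


def test_production_envelope_matches_closed_form_line():
    for yb, yp in [(1.0, 1.0), (1.0, 0.5), (2.0, 2.0)]:
        model = make_production_branch(10.0, yb, yp)
        env = production_envelope(model, Medium({"EX_A_e": 10.0}), "DM_P_c", 11)
        for mu, lo, hi in env.points:
            assert hi == pytest.approx(yp * (10.0 - mu / yb), abs=1e-9)
            assert lo == pytest.approx(0.0, abs=1e-9)


def test_envelope_endpoints_equal_max_production(toyprod):
    medium = Medium({"EX_A_e": 10.0})
    env = production_envelope(toyprod, medium, "DM_P_c", 2)
    at_zero = max_production(toyprod, medium, "DM_P_c", 0.0).objective_value
    at_full = max_production(toyprod, medium, "DM_P_c", 1.0).objective_value
    assert env.points[0][2] == pytest.approx(at_zero, abs=TOL)
    assert env.points[-1][2] == pytest.approx(at_full, abs=TOL)


def test_envelope_max_non_increasing_for_single_substrate(toyprod):
    env = production_envelope(toyprod, Medium({"EX_A_e": 10.0}), "DM_P_c", 11)
    maxima = [hi for _, _, hi in env.points]
    assert all(b <= a + TOL for a, b in zip(maxima, maxima[1:]))


def test_envelope_needs_two_points(toyprod):
    with pytest.raises(ValueError, match="n_points"):
        production_envelope(toyprod, Medium({"EX_A_e": 10.0}), "DM_P_c", 1)


# -- phase plane ----------------------------------------------------------


def test_phase_plane_follows_min_rule(cntoy):
    medium = Medium({"EX_C_e": 10.0, "EX_N_e": 4.0})
    grid = phase_plane(cntoy, medium, "EX_N_e", [0.0, 2.0, 4.0, 6.0, 10.0, 15.0], "DM_P_c")
    for _, row in grid.iterrows():
        n = row["axis_value"]
        expected_growth = min(10.0, n)
        assert row["growth"] == pytest.approx(expected_growth, abs=TOL)
        assert row["target_max_at_optimum"] == pytest.approx(
            10.0 - expected_growth, abs=TOL
        )
        assert row["target_max_unconstrained"] == pytest.approx(10.0, abs=TOL)


def test_phase_plane_nitrogen_starvation_limit(cntoy):
    """Zero nitrogen: no growth, carbon-only product bound."""
    grid = phase_plane(cntoy, Medium({"EX_C_e": 10.0}), "EX_N_e", [0.0], "DM_P_c")
    assert grid.loc[0, "growth"] == pytest.approx(0.0, abs=TOL)
    assert grid.loc[0, "target_max_at_optimum"] == pytest.approx(10.0, abs=TOL)


def test_phase_plane_rejects_bad_axis_values(cntoy):
    medium = Medium({"EX_C_e": 10.0})
    with pytest.raises(ValueError, match="increasing"):
        phase_plane(cntoy, medium, "EX_N_e", [4.0, 2.0], "DM_P_c")
    with pytest.raises(ValueError, match=">= 0"):
        phase_plane(cntoy, medium, "EX_N_e", [-1.0, 2.0], "DM_P_c")
    with pytest.raises(ValueError, match="exchange"):
        phase_plane(cntoy, medium, "BIOMASS", [0.0, 1.0], "DM_P_c")
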