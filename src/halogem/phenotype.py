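"""Simulation protocols for growth phenotyping and production fitness.

The battery mirrors how constraint-based models of industrial halophiles
are interrogated: define a medium through exchange-reaction uptake
bounds, reduce it to a minimal growth-supporting set, screen sole carbon
sources one at a time, test anaerobic growth with candidate electron
acceptors, probe maximal production of compatible solutes and storage
polymers through demand reactions, and trace growth-versus-production
trade-off envelopes and two-flux phase planes.

Media use the standard sign convention: an uptake limit ``u`` for an
exchange reaction is applied as lower bound ``-u`` (negative flux =
uptake); secretion is never restricted by a medium.  Growth calls use a
zero-growth threshold of 1e-6 1/h: a predicted flux below it counts as
"no growth".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lp import (
    TOLERANCE,
    FluxSolution,
    StoichiometricSystem,
    build_system,
    solve_fba,
)
from .model import (
    DEFAULT_UPPER,
    SBO_DEMAND,
    MetabolicModel,
    Reaction,
)

__all__ = [
    "GROWTH_THRESHOLD",
    "Medium",
    "ScreenRow",
    "ScreenResult",
    "Envelope",
    "MinimalMediumResult",
    "set_medium",
    "grows_on",
    "determine_minimal_medium",
    "carbon_secretion_check",
    "carbon_source_screen",
    "anaerobic_growth_test",
    "add_demand_reaction",
    "max_production",
    "production_envelope",
    "phase_plane",
]

#: a predicted growth flux below this (1/h) counts as "no growth"
GROWTH_THRESHOLD = 1e-6


@dataclass
class Medium:
    """Uptake limits per exchange reaction, mmol/gDW/h (positive).

    Exchange reactions not listed are closed for uptake (lower bound 0);
    their secretion direction is untouched.
    """

    uptake_limits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, rate in self.uptake_limits.items():
            if rate < 0:
                raise ValueError(f"uptake limit for {rid} must be >= 0, got {rate}")

    def __contains__(self, rid: str) -> bool:
        return rid in self.uptake_limits

    def __iter__(self):
        return iter(self.uptake_limits)

    def without(self, rid: str) -> "Medium":
        limits = dict(self.uptake_limits)
        limits.pop(rid, None)
        return Medium(limits)

    def updated(self, rid: str, rate: float) -> "Medium":
        limits = dict(self.uptake_limits)
        limits[rid] = rate
        return Medium(limits)


@dataclass
class ScreenRow:
    condition: str
    growth: float
    grows: bool
    note: str = ""


@dataclass
class ScreenResult:
    rows: list[ScreenRow]
    threshold: float = GROWTH_THRESHOLD

    def row(self, condition: str) -> ScreenRow:
        for r in self.rows:
            if r.condition == condition:
                return r
        raise KeyError(condition)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.condition, r.growth, r.grows, r.note) for r in self.rows],
            columns=["condition", "growth", "grows", "note"],
        )


@dataclass
class Envelope:
    """Trade-off grid: target flux range at each constrained value."""

    constrained: str
    target: str
    points: list[tuple[float, float, float]]  # (constrained value, min, max)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=[self.constrained, "target_min", "target_max"]
        )


@dataclass
class AuditRow:
    component: str
    growth_without: float
    essential: bool
    restored: bool = False


@dataclass
class MinimalMediumResult:
    medium: Medium
    audit: list[AuditRow]
    growth_on_minimal: float
    secreted_carbon: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (a.component, a.growth_without, a.essential, a.restored)
                for a in self.audit
            ],
            columns=["component", "growth_without", "essential", "restored"],
        )


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------

def set_medium(model: MetabolicModel, medium: Medium) -> dict[str, tuple[float, float]]:
    """Bound overrides realizing a medium on a model.

    Every exchange reaction not named in the medium gets lower bound 0
    (uptake closed, secretion still allowed); named exchanges get lower
    bound ``-rate``.  Upper bounds are never modified.  Naming a
    non-exchange reaction is a contract error.
    """
    exchange_ids = {r.id for r in model.exchanges()}
    for rid in medium:
        if not model.has_reaction(rid):
            raise ValueError(f"medium names unknown reaction {rid!r}")
        if rid not in exchange_ids:
            raise ValueError(f"medium names non-exchange reaction {rid!r}")
    overrides: dict[str, tuple[float, float]] = {}
    for rxn in model.exchanges():
        rate = medium.uptake_limits.get(rxn.id, 0.0)
        overrides[rxn.id] = (-rate, rxn.upper_bound)
    return overrides


def _system_on_medium(model: MetabolicModel, medium: Medium) -> StoichiometricSystem:
    return build_system(model).with_bounds(set_medium(model, medium))


def grows_on(
    model: MetabolicModel, medium: Medium, threshold: float = GROWTH_THRESHOLD
) -> tuple[float, bool]:
    """FBA growth value on a medium and the grows/no-grows call."""
    solution = solve_fba(_system_on_medium(model, medium))
    growth = solution.objective_value if solution.optimal else 0.0
    return growth, growth >= threshold


# ---------------------------------------------------------------------------
# minimal medium
# ---------------------------------------------------------------------------

def determine_minimal_medium(
    model: MetabolicModel,
    full_medium: Medium,
    carbon_source: str,
    threshold: float = GROWTH_THRESHOLD,
) -> MinimalMediumResult:
    """Reduce a rich medium to its essential components.

    The carbon source stays open throughout.  Each other component is
    closed alone and growth re-optimized; the component is essential iff
    growth falls below the threshold.  The candidate minimal medium is
    the carbon source plus all essential components.  Because
    per-component tests cannot resolve interchangeable nutrients (two
    substitutable sources each test non-essential yet one is needed), a
    joint check follows: if the candidate set does not support growth,
    non-essential components are restored greedily in audit order until
    it does, and every restoration is flagged.  Finally the optimum on
    the minimal medium is checked for carbon secretion other than CO2.
    """
    if carbon_source not in full_medium:
        raise ValueError(f"carbon source {carbon_source!r} is not in the full medium")
    growth, ok = grows_on(model, full_medium, threshold)
    if not ok:
        raise ValueError(
            f"model does not grow on the full medium (growth {growth:.3g}); "
            "check the medium before minimizing it"
        )

    audit: list[AuditRow] = []
    for component in full_medium:
        if component == carbon_source:
            continue
        reduced = full_medium.without(component)
        g, grows = grows_on(model, reduced, threshold)
        audit.append(AuditRow(component=component, growth_without=g, essential=not grows))

    minimal = Medium(
        {
            rid: rate
            for rid, rate in full_medium.uptake_limits.items()
            if rid == carbon_source
            or any(a.component == rid and a.essential for a in audit)
        }
    )

    g, grows = grows_on(model, minimal, threshold)
    if not grows:
        for row in audit:
            if row.essential or row.component in minimal:
                continue
            minimal = minimal.updated(
                row.component, full_medium.uptake_limits[row.component]
            )
            row.restored = True
            g, grows = grows_on(model, minimal, threshold)
            if grows:
                break
    if not grows:
        raise RuntimeError("could not recover growth on any restored medium")

    solution = solve_fba(_system_on_medium(model, minimal))
    secreted = carbon_secretion_check(model, solution)
    return MinimalMediumResult(
        medium=minimal, audit=audit, growth_on_minimal=g, secreted_carbon=secreted
    )


_CO2_COMPOSITIONS = ({"C": 1, "O": 2},)


def carbon_secretion_check(
    model: MetabolicModel, solution: FluxSolution, tolerance: float = TOLERANCE
) -> list[dict]:
    """Carbon-bearing compounds secreted in a flux solution, CO2 excluded.

    Returns one record per offending exchange: id, metabolite, rate, and
    formula status.  Exchanged species without a parseable formula are
    reported with status ``unknown-formula`` rather than silently
    passed.  An empty list means only CO2 (or nothing) leaves the cell.
    """
    offending: list[dict] = []
    for rxn in model.exchanges():
        rate = solution.fluxes.get(rxn.id, 0.0)
        if rate <= tolerance:
            continue
        (met_id,) = rxn.stoichiometry
        met = model.metabolite(met_id)
        elements = met.elements()
        if elements is None:
            offending.append(
                {
                    "exchange": rxn.id,
                    "metabolite": met_id,
                    "rate": rate,
                    "status": "unknown-formula",
                }
            )
        elif elements.get("C", 0) > 0 and elements not in _CO2_COMPOSITIONS:
            offending.append(
                {
                    "exchange": rxn.id,
                    "metabolite": met_id,
                    "rate": rate,
                    "status": "carbon-secretion",
                }
            )
    return offending


# ---------------------------------------------------------------------------
# carbon-source and anaerobic screens
# ---------------------------------------------------------------------------

def carbon_source_screen(
    model: MetabolicModel,
    minimal: Medium,
    candidates: list[str],
    uptake: float = 10.0,
    threshold: float = GROWTH_THRESHOLD,
) -> ScreenResult:
    """Growth screen over sole carbon sources.

    Each candidate exchange is opened at the uniform uptake rate
    (10 mmol/gDW/h by default) on top of the minimal medium with every
    other candidate closed, and growth is re-optimized.  Candidates
    absent from the model are recorded with note ``not in model``.
    """
    in_model = [c for c in candidates if model.has_reaction(c)]
    rows: list[ScreenRow] = []
    base = {
        rid: rate for rid, rate in minimal.uptake_limits.items() if rid not in candidates
    }
    for candidate in candidates:
        if candidate not in in_model:
            rows.append(
                ScreenRow(condition=candidate, growth=float("nan"), grows=False, note="not in model")
            )
            continue
        medium = Medium({**base, candidate: uptake})
        growth, grows = grows_on(model, medium, threshold)
        rows.append(ScreenRow(condition=candidate, growth=growth, grows=grows))
    return ScreenResult(rows=rows, threshold=threshold)


def anaerobic_growth_test(
    model: MetabolicModel,
    medium: Medium,
    electron_acceptors: list[str],
    oxygen_exchange: str = "EX_o2_e",
    uptake: float = 10.0,
    threshold: float = GROWTH_THRESHOLD,
) -> ScreenResult:
    """Growth with oxygen uptake closed, alone and per electron acceptor.

    The oxygen exchange's uptake is shut; the first row is the plain
    anaerobic condition, followed by one row per candidate acceptor
    opened at the stated uptake rate (the same rate used for the carbon
    source).  A model without the named oxygen exchange is a contract
    error.
    """
    if not model.has_reaction(oxygen_exchange):
        raise ValueError(f"model has no oxygen exchange reaction {oxygen_exchange!r}")
    anaerobic = medium.without(oxygen_exchange)
    rows: list[ScreenRow] = []
    growth, grows = grows_on(model, anaerobic, threshold)
    rows.append(ScreenRow(condition="anaerobic", growth=growth, grows=grows))
    for acceptor in electron_acceptors:
        if not model.has_reaction(acceptor):
            rows.append(
                ScreenRow(condition=f"anaerobic+{acceptor}", growth=float("nan"), grows=False, note="not in model")
            )
            continue
        medium_a = anaerobic.updated(acceptor, uptake)
        growth, grows = grows_on(model, medium_a, threshold)
        rows.append(ScreenRow(condition=f"anaerobic+{acceptor}", growth=growth, grows=grows))
    return ScreenResult(rows=rows, threshold=threshold)


# ---------------------------------------------------------------------------
# production
# ---------------------------------------------------------------------------

def add_demand_reaction(model: MetabolicModel, metabolite_id: str) -> str:
    """Add an irreversible sink ``DM_<met>: met -> (nothing)`` in place.

    Demand reactions probe the maximal achievable synthesis rate of an
    intracellular compound (here typically ectoine, 5-hydroxyectoine or
    PHB).  At the wildtype optimum the new sink carries zero flux, so
    adding it never changes the growth optimum.  Returns the new
    reaction id; adding a second demand for the same metabolite is a
    contract error.
    """
    met = model.metabolite(metabolite_id)  # raises KeyError when absent
    demand_id = f"DM_{met.id}"
    if model.has_reaction(demand_id):
        raise ValueError(f"demand reaction {demand_id!r} already present")
    model.reactions.append(
        Reaction(
            id=demand_id,
            name=f"{met.name or met.id} demand",
            stoichiometry={met.id: -1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_UPPER,
            sbo_term=SBO_DEMAND,
        )
    )
    return demand_id


def max_production(
    model: MetabolicModel,
    medium: Medium,
    target: str,
    growth_requirement: float = 0.0,
) -> FluxSolution:
    """Maximal flux through a target reaction at a required growth level.

    The biomass flux is constrained to at least ``growth_requirement``
    times the wildtype optimum, the objective is switched to the target
    reaction and maximized.  ``growth_requirement=0`` probes production
    with growth unconstrained (its lowest possible value).  An
    infeasible combination is reported through the solution status, not
    as an exception.
    """
    if not model.has_reaction(target):
        raise KeyError(f"no reaction {target!r} in model")
    if not 0.0 <= growth_requirement <= 1.0:
        raise ValueError("growth_requirement must lie in [0, 1]")
    system = _system_on_medium(model, medium)
    biomass = model.biomass_reaction()
    jb = system.col_index[biomass.id]
    if growth_requirement > 0.0:
        wildtype = solve_fba(system)
        if not wildtype.optimal or wildtype.objective_value < GROWTH_THRESHOLD:
            raise ValueError(
                "wildtype does not grow on this medium; cannot require a growth fraction"
            )
        system = system.copy()
        system.lower[jb] = max(
            system.lower[jb], growth_requirement * wildtype.objective_value
        )
    jt = system.col_index[target]
    c = np.zeros(system.n_reactions)
    c[jt] = 1.0
    production = system.copy()
    production.objective = c
    return solve_fba(production)


def production_envelope(
    model: MetabolicModel,
    medium: Medium,
    target: str,
    n_points: int = 11,
) -> Envelope:
    """Target flux range as biomass sweeps 0 .. wildtype optimum.

    At each of ``n_points`` evenly spaced biomass values the biomass
    flux is pinned and the target minimized and maximized.  A solver
    failure at one grid point is recorded as a gap (NaN), not a failure
    of the whole envelope.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    system = _system_on_medium(model, medium)
    biomass = model.biomass_reaction()
    wildtype = solve_fba(system)
    if not wildtype.optimal or wildtype.objective_value < GROWTH_THRESHOLD:
        raise ValueError("wildtype does not grow on this medium")
    jb = system.col_index[biomass.id]
    jt = system.col_index[target]

    points: list[tuple[float, float, float]] = []
    for mu in np.linspace(0.0, wildtype.objective_value, n_points):
        pinned = system.copy()
        pinned.lower[jb] = mu
        pinned.upper[jb] = mu
        c = np.zeros(system.n_reactions)
        c[jt] = 1.0
        pinned.objective = c
        lo = solve_fba(pinned, "minimize")
        hi = solve_fba(pinned, "maximize")
        points.append(
            (
                float(mu),
                lo.objective_value if lo.optimal else float("nan"),
                hi.objective_value if hi.optimal else float("nan"),
            )
        )
    return Envelope(constrained=biomass.id, target=target, points=points)


def phase_plane(
    model: MetabolicModel,
    medium: Medium,
    axis_reaction: str,
    axis_values: list[float],
    target: str,
) -> pd.DataFrame:
    """Two-flux phase plane: vary one uptake, watch growth and a target.

    For each axis value (an uptake limit, so values must be
    non-negative and strictly increasing) the axis exchange is bounded,
    growth maximized, and the maximal target flux recorded both at that
    growth optimum and with growth left unconstrained.  Typical use:
    ammonium uptake versus PHB synthesis, where storage-polymer
    production rises as nitrogen becomes scarce.
    """
    exchange_ids = {r.id for r in model.exchanges()}
    if axis_reaction not in exchange_ids:
        raise ValueError(f"{axis_reaction!r} is not an exchange reaction")
    values = list(axis_values)
    if any(v < 0 for v in values):
        raise ValueError("axis values are uptake limits and must be >= 0")
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError("axis values must be strictly increasing")

    biomass = model.biomass_reaction()
    rows = []
    for value in values:
        medium_v = medium.updated(axis_reaction, value)
        system = _system_on_medium(model, medium_v)
        jb = system.col_index[biomass.id]
        jt = system.col_index[target]
        growth_sol = solve_fba(system)
        growth = growth_sol.objective_value if growth_sol.optimal else float("nan")

        c = np.zeros(system.n_reactions)
        c[jt] = 1.0

        at_optimum = float("nan")
        if growth_sol.optimal:
            pinned = system.copy()
            pinned.lower[jb] = growth
            pinned.upper[jb] = growth
            pinned.objective = c
            sol = solve_fba(pinned)
            if sol.optimal:
                at_optimum = sol.objective_value

        free = system.copy()
        free.objective = c
        sol_free = solve_fba(free)
        unconstrained = sol_free.objective_value if sol_free.optimal else float("nan")

        rows.append(
            {
                "axis_value": value,
                "growth": growth,
                "target_max_at_optimum": at_optimum,
                "target_max_unconstrained": unconstrained,
            }
        )
    return pd.DataFrame(rows)
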