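"""Literature-validation battery and its report.

``run_validation_battery`` executes a configured list of checks --
blocked-metabolite count, parsed gene count, a sole-carbon-source
screen with per-compound grows/does-not-grow expectations, anaerobic
tests, an essential-gene count and demand-reaction production maxima --
against a model, comparing each computed value with its configured
expectation.  Every stage runs on an independent copy of the model so
bound edits can never leak between stages, which also makes the whole
battery deterministic: running it twice yields identical reports.

Flux-valued expectations compare at 0.01 mmol/gDW/h, matching the
two-decimal precision such rates are conventionally reported at.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import math
import os
from dataclasses import asdict, dataclass, field

from . import __version__
from .essentiality import single_gene_essentiality
from .lp import build_system, find_blocked_metabolites, find_blocked_reactions
from .model import MetabolicModel
from .phenotype import (
    GROWTH_THRESHOLD,
    Medium,
    add_demand_reaction,
    anaerobic_growth_test,
    carbon_source_screen,
    max_production,
)

__all__ = ["CheckRow", "ValidationReport", "run_validation_battery", "load_config"]

FLUX_TOLERANCE = 0.01


@dataclass
class CheckRow:
    name: str
    expected: object
    computed: object
    comparator: str
    passed: bool
    note: str = ""


@dataclass
class ValidationReport:
    rows: list[CheckRow]
    provenance: dict = field(default_factory=dict)

    @property
    def n_passed(self) -> int:
        return sum(r.passed for r in self.rows)

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "provenance": self.provenance,
                "n_passed": self.n_passed,
                "n_checks": len(self.rows),
                "checks": [asdict(r) for r in self.rows],
            },
            indent=2,
            default=str,
        )

    def to_text(self) -> str:
        lines = [f"validation report ({self.n_passed}/{len(self.rows)} passed)"]
        for r in self.rows:
            mark = "PASS" if r.passed else "FAIL"
            line = f"  [{mark}] {r.name}: expected {r.expected} ({r.comparator}), computed {r.computed}"
            if r.note:
                line += f"  # {r.note}"
            lines.append(line)
        return "\n".join(lines)


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _file_sha256(path: str | os.PathLike | None) -> str | None:
    if path is None or not os.path.exists(path):
        return None
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _compare(computed, expected, comparator: str, tolerance: float) -> bool:
    if comparator == "equal_count":
        return int(computed) == int(expected)
    if comparator == "within_tolerance":
        return (
            isinstance(computed, (int, float))
            and not math.isnan(float(computed))
            and abs(float(computed) - float(expected)) <= tolerance
        )
    if comparator == "grows":
        return bool(computed) is True
    if comparator == "does_not_grow":
        return bool(computed) is False
    if comparator == "not_in_model":
        return computed == "not in model"
    raise ValueError(f"unknown comparator {comparator!r}")


def run_validation_battery(
    model: MetabolicModel,
    config: dict,
    model_path: str | os.PathLike | None = None,
) -> ValidationReport:
    """Run every configured check and assemble the report.

    ``config`` layout (all sections optional)::

        {
          "medium": {"EX_glc__D_e": 10, ...},
          "carbon_source": "EX_glc__D_e",
          "oxygen_exchange": "EX_o2_e",
          "expectations": {
            "gene_count": 1159,
            "blocked_metabolite_count": 37,
            "essential_gene_count": 60,
            "anaerobic_no_growth": true,
            "electron_acceptors": ["EX_no3_e"],
            "carbon_sources": {"EX_glc__D_e": "grows", ...},
            "production": [
              {"metabolite": "ectoine_c", "maximum": 7.05,
               "growth_requirement": 0.0}
            ]
          }
        }

    A crash inside one stage marks its row(s) ``error`` and the battery
    continues; no configured row is ever dropped.  Demand reactions
    named by production checks are added when absent (detect-and-add).
    """
    medium = Medium({k: float(v) for k, v in config.get("medium", {}).items()})
    expectations = config.get("expectations", {})
    threshold = float(config.get("growth_threshold", GROWTH_THRESHOLD))
    rows: list[CheckRow] = []

    def run_stage(fn, *rows_on_error: CheckRow):
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - report, never abort the battery
            for row in rows_on_error:
                row.note = f"error: {exc}"
                rows.append(row)

    if "gene_count" in expectations:
        expected = expectations["gene_count"]
        computed = len(model.genes)
        rows.append(
            CheckRow(
                "gene_count",
                expected,
                computed,
                "equal_count",
                _compare(computed, expected, "equal_count", 0),
            )
        )

    if "blocked_metabolite_count" in expectations:
        expected = expectations["blocked_metabolite_count"]

        def stage():
            work = model.copy()
            blocked_rxns = find_blocked_reactions(build_system(work))
            blocked_mets = find_blocked_metabolites(work, blocked_rxns)
            computed = len(blocked_mets)
            rows.append(
                CheckRow(
                    "blocked_metabolite_count",
                    expected,
                    computed,
                    "equal_count",
                    _compare(computed, expected, "equal_count", 0),
                )
            )

        run_stage(
            stage,
            CheckRow("blocked_metabolite_count", expected, "error", "equal_count", False),
        )

    carbon_expect = expectations.get("carbon_sources", {})
    if carbon_expect:

        def stage():
            work = model.copy()
            screen = carbon_source_screen(
                work,
                medium,
                list(carbon_expect),
                uptake=float(config.get("carbon_uptake", 10.0)),
                threshold=threshold,
            )
            for candidate, expected in carbon_expect.items():
                row = screen.row(candidate)
                computed = "not in model" if row.note == "not in model" else row.grows
                comparator = {
                    "grows": "grows",
                    "does_not_grow": "does_not_grow",
                    "not_in_model": "not_in_model",
                }[expected]
                rows.append(
                    CheckRow(
                        f"carbon_source:{candidate}",
                        expected,
                        computed,
                        comparator,
                        _compare(computed, expected, comparator, 0),
                    )
                )

        run_stage(
            stage,
            *[
                CheckRow(f"carbon_source:{c}", e, "error", e, False)
                for c, e in carbon_expect.items()
            ],
        )

    if expectations.get("anaerobic_no_growth"):
        acceptors = expectations.get("electron_acceptors", [])

        def stage():
            work = model.copy()
            screen = anaerobic_growth_test(
                work,
                medium,
                acceptors,
                oxygen_exchange=config.get("oxygen_exchange", "EX_o2_e"),
                uptake=float(config.get("carbon_uptake", 10.0)),
                threshold=threshold,
            )
            for row in screen.rows:
                rows.append(
                    CheckRow(
                        row.condition,
                        "does_not_grow",
                        row.grows,
                        "does_not_grow",
                        _compare(row.grows, None, "does_not_grow", 0),
                        note=row.note,
                    )
                )

        run_stage(
            stage,
            CheckRow("anaerobic", "does_not_grow", "error", "does_not_grow", False),
        )

    if "essential_gene_count" in expectations:
        expected = expectations["essential_gene_count"]

        def stage():
            work = model.copy()
            result = single_gene_essentiality(work, medium, threshold=threshold)
            computed = len(result.essential)
            rows.append(
                CheckRow(
                    "essential_gene_count",
                    expected,
                    computed,
                    "equal_count",
                    _compare(computed, expected, "equal_count", 0),
                )
            )

        run_stage(
            stage,
            CheckRow("essential_gene_count", expected, "error", "equal_count", False),
        )

    for production in expectations.get("production", []):
        met_id = production["metabolite"]
        expected = production["maximum"]

        def stage(met_id=met_id, expected=expected, production=production):
            work = model.copy()
            demand_id = f"DM_{met_id}"
            if not work.has_reaction(demand_id):
                demand_id = add_demand_reaction(work, met_id)
            solution = max_production(
                work,
                medium,
                demand_id,
                growth_requirement=float(production.get("growth_requirement", 0.0)),
            )
            computed = solution.objective_value if solution.optimal else float("nan")
            rows.append(
                CheckRow(
                    f"production:{met_id}",
                    expected,
                    round(computed, 4) if computed == computed else computed,
                    "within_tolerance",
                    _compare(computed, expected, "within_tolerance", FLUX_TOLERANCE),
                )
            )

        run_stage(
            stage,
            CheckRow(f"production:{met_id}", expected, "error", "within_tolerance", False),
        )

    provenance = {
        "model_id": model.id,
        "model_file_sha256": _file_sha256(model_path),
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "tool_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return ValidationReport(rows=rows, provenance=provenance)
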