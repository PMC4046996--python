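"""Scenario analyses: the base case, the five one-way sensitivity analyses,
and the cost-perspective variants, as declarative parameter overrides.

Each scenario replaces a handful of parameters with fixed values and leaves
everything else — including the random seed and the effectiveness posterior —
untouched, so scenario contrasts isolate exactly the overridden assumptions:

- ``base``: no overrides;
- ``SA1``: smoke-alarm prevalence reduced from 80% to 50%;
- ``SA2``: probability of accepting the intervention reduced from 90% to 50%;
- ``SA3``: decay/repair of safety equipment reduced from 0.1 to zero;
- ``SA4``: children under 5 per household increased from 1 to 1.8;
- ``SA5``: same probability of injury following a fire (0.91) whether or not
  a functioning alarm is present.  By default SA5 equalises only the injury
  probability, leaving the severity splits alarm-specific; pass
  ``equalise_severity=True`` to equalise those too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import CEACResult, EVPIResult, FrontierResult, ceac, compute_frontier, evpi
from .fixture import DEFAULT_N_DRAWS, DEFAULT_SEED, ModelInputs, default_inputs
from .parameters import ParameterTable
from .psa import PSAResult, Settings, run_psa

__all__ = [
    "Scenario",
    "SCENARIOS",
    "apply_scenario",
    "ScenarioRun",
    "run_scenario",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_EVPI_THRESHOLD",
]

#: CEAC threshold grid, GBP per QALY
DEFAULT_THRESHOLDS = np.arange(0.0, 100001.0, 1000.0)
#: headline willingness-to-pay threshold for EVPI reporting, GBP per QALY
DEFAULT_EVPI_THRESHOLD = 30000.0


@dataclass(frozen=True)
class Scenario:
    """A named set of fixed-value parameter overrides."""

    name: str
    overrides: dict = field(default_factory=dict)
    description: str = ""


SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in (
        Scenario("base", {}, "base case"),
        Scenario("SA1", {"p_prev": 0.5}, "alarm prevalence 80% -> 50%"),
        Scenario("SA2", {"p_accept": 0.5}, "acceptance 90% -> 50%"),
        Scenario("SA3", {"d_decay": 0.0, "d_repair": 0.0}, "equipment decay/repair -> 0"),
        Scenario("SA4", {"h": 1.8}, "children per household 1 -> 1.8"),
        Scenario(
            "SA5",
            {"p_injury_func": 0.91, "p_injury_nonfunc": 0.91},
            "equal injury probability (0.91) regardless of alarm state",
        ),
    )
}


def apply_scenario(
    scenario: Scenario | str, table: ParameterTable, equalise_severity: bool = False
) -> ParameterTable:
    """Return the table with the scenario's parameters pinned to fixed values."""
    if isinstance(scenario, str):
        if scenario not in SCENARIOS:
            raise KeyError(
                f"unknown scenario {scenario!r}; valid names: {sorted(SCENARIOS)}"
            )
        scenario = SCENARIOS[scenario]
    out = table.override(scenario.overrides)
    if equalise_severity:
        out = out.replace_spec("severity_split_nonfunc", out["severity_split_func"].spec)
    return out


@dataclass
class ScenarioRun:
    """End-to-end scenario output: PSA matrix plus all decision analytics."""

    scenario: Scenario
    psa: PSAResult
    frontier: FrontierResult
    ceac: CEACResult
    evpi: EVPIResult

    def report(self) -> pd.DataFrame:
        """Incremental-analysis table augmented with CEAC columns at 30k/50k."""
        table = self.frontier.table()
        for lam in (30000.0, 50000.0):
            probs = self.ceac.at(lam)
            table[f"prob_ce_{int(lam)}"] = [probs[s] for s in table["strategy"]]
        return table

    def summary(self) -> str:
        lines = [
            f"scenario: {self.scenario.name} ({self.scenario.description})",
            f"perspective: {self.psa.settings['perspective']}, "
            f"n_draws: {self.psa.settings['n_draws']}, seed: {self.psa.settings['seed']}",
            self.report().to_string(index=False, float_format=lambda x: f"{x:,.3f}"),
            f"per-decision EVPI at GBP {self.evpi.threshold:,.0f}/QALY: "
            f"GBP {self.evpi.per_decision:,.2f} per household",
        ]
        return "\n".join(lines)


def run_scenario(
    scenario: Scenario | str,
    inputs: ModelInputs | None = None,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = DEFAULT_SEED,
    perspective: str = "public_sector",
    thresholds=None,
    evpi_threshold: float = DEFAULT_EVPI_THRESHOLD,
    equalise_severity: bool = False,
) -> ScenarioRun:
    """Run one scenario end to end on the given (or default synthetic) inputs."""
    if isinstance(scenario, str):
        if scenario not in SCENARIOS:
            raise KeyError(
                f"unknown scenario {scenario!r}; valid names: {sorted(SCENARIOS)}"
            )
        scenario = SCENARIOS[scenario]
    if inputs is None:
        inputs = default_inputs(n_draws=n_draws, seed=seed)
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    table = apply_scenario(scenario, inputs.table, equalise_severity=equalise_severity)
    settings = Settings(
        n_draws=n_draws,
        seed=seed,
        perspective=perspective,
        scenario=scenario.name,
        equalise_severity=equalise_severity,
    )
    psa = run_psa(table, inputs.posterior, inputs.life_table, inputs.utility_norms, settings)
    means = psa.mean_outcomes()
    frontier = compute_frontier(
        means["mean_qalys"].to_numpy(), means["mean_cost"].to_numpy(), psa.labels
    )
    curves = ceac(psa, thresholds)
    information = evpi(psa, evpi_threshold)
    return ScenarioRun(scenario=scenario, psa=psa, frontier=frontier, ceac=curves, evpi=information)
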