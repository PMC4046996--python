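"""Probabilistic sensitivity analysis engine.

Composes the three model stages per strategy per parameter draw, applies the
children-per-household multiplier and the cost-perspective filter, and builds
the draws x strategies outcome matrix that all decision analytics consume.

Per-child quantities (QALYs and the costs that follow the injured child —
treatment, ongoing care, fatality and productivity costs) scale with ``h``,
the number of under-5 children per household; household-level quantities
(intervention delivery, fire & rescue attendance, property damage) do not.
Parameter draw *i* is paired with posterior row *i*, mirroring the coupling of
the decision model to the MCMC output of the effectiveness synthesis; the
number of model simulations therefore equals the number of posterior draws.

Cost perspectives select which cost categories count towards a strategy's
total.  Intervention delivery cost is included under every perspective:

- ``public_sector`` (base case): NHS/PSS plus other public-sector costs such
  as fire & rescue attendance;
- ``NHS_PSS``: healthcare-related costs only, omitting fire & rescue;
- ``extended_household``: public sector plus costs falling on the household
  (property damage, fatality costs, equipment) but never lost productivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import LifeTable, UtilityNorms
from .lifetime import run_lifetime
from .parameters import COST_CATEGORIES, ParameterDraw, ParameterTable, sample_draw
from .posterior import EffectivenessPosterior
from .preschool import run_preschool
from .tree import STRATEGIES, StrategySpec, evaluate_tree

__all__ = [
    "PERSPECTIVES",
    "Settings",
    "CohortOutcome",
    "PSAResult",
    "evaluate_strategy",
    "run_psa",
]

#: cost categories counted under each perspective (intervention cost always counts)
PERSPECTIVES = {
    "public_sector": ("NHS_PSS", "other_public"),
    "NHS_PSS": ("NHS_PSS",),
    "extended_household": ("NHS_PSS", "other_public", "household"),
}


@dataclass
class Settings:
    """Run configuration snapshot recorded alongside every PSA result."""

    n_draws: int = 5000
    seed: int = 20140516
    perspective: str = "public_sector"
    scenario: str = "base"
    charge_nonacceptors: bool = False
    #: tie the realised severity splits of the two alarm states (full SA5 variant)
    equalise_severity: bool = False

    def __post_init__(self) -> None:
        if self.perspective not in PERSPECTIVES:
            raise ValueError(
                f"unknown perspective {self.perspective!r}; "
                f"expected one of {sorted(PERSPECTIVES)}"
            )
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class CohortOutcome:
    """Expected discounted QALYs and itemised costs per household, one strategy."""

    strategy_id: int
    qalys: float | np.ndarray
    cost_intervention: float | np.ndarray
    costs: dict = field(default_factory=dict)

    def total_cost(self, perspective: str = "public_sector"):
        included = PERSPECTIVES[perspective]
        return self.cost_intervention + sum(self.costs[c] for c in included)


def evaluate_strategy(
    strategy: StrategySpec,
    draw: ParameterDraw,
    pi_k,
    life_table: LifeTable,
    settings: Settings | None = None,
) -> CohortOutcome:
    """Tree -> pre-school -> lifetime for one strategy under one draw (or batch)."""
    settings = settings or Settings()
    tree = evaluate_tree(
        strategy, draw, pi_k, charge_nonacceptors=settings.charge_nonacceptors
    )
    pre = run_preschool(tree, draw, life_table)
    life = run_lifetime(pre.terminal, draw, life_table)
    h = draw.h
    qalys = h * (pre.qalys + life.qalys)
    costs = {
        c: h * (pre.costs_child[c] + life.costs_child[c]) + pre.costs_household[c]
        for c in COST_CATEGORIES
    }
    return CohortOutcome(
        strategy_id=strategy.id,
        qalys=qalys,
        cost_intervention=tree.cost_intervention,
        costs=costs,
    )


@dataclass
class PSAResult:
    """Outcome matrices over draws x strategies plus the settings snapshot."""

    qalys: np.ndarray
    cost_intervention: np.ndarray
    costs: dict
    labels: tuple[str, ...]
    settings: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.qalys.shape[0]

    @property
    def n_strategies(self) -> int:
        return self.qalys.shape[1]

    def total_costs(self, perspective: str | None = None) -> np.ndarray:
        """Per-draw per-strategy total cost under a perspective (default: the run's)."""
        perspective = perspective or self.settings.get("perspective", "public_sector")
        included = PERSPECTIVES[perspective]
        return self.cost_intervention + sum(self.costs[c] for c in included)

    def mean_outcomes(self, perspective: str | None = None) -> pd.DataFrame:
        """Per-strategy mean QALYs and mean total costs across draws."""
        return pd.DataFrame(
            {
                "strategy": self.labels,
                "mean_qalys": self.qalys.mean(axis=0),
                "mean_cost": self.total_costs(perspective).mean(axis=0),
            }
        )

    def scaled(self, factor: float) -> "PSAResult":
        """Affine rescaling of every outcome (e.g. per-household -> per-cohort)."""
        return PSAResult(
            qalys=self.qalys * factor,
            cost_intervention=self.cost_intervention * factor,
            costs={c: v * factor for c, v in self.costs.items()},
            labels=self.labels,
            settings=dict(self.settings),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: draw, strategy, qalys, cost columns."""
        n, k = self.qalys.shape
        frame = pd.DataFrame(
            {
                "draw": np.repeat(np.arange(n), k),
                "strategy": np.tile(self.labels, n),
                "qalys": self.qalys.ravel(),
                "cost_total": self.total_costs().ravel(),
                "cost_intervention": self.cost_intervention.ravel(),
            }
        )
        for c in COST_CATEGORIES:
            frame[f"cost_{c}"] = self.costs[c].ravel()
        return frame

    def to_csv(self, path, metadata_path=None) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                json.dump(self.settings, fh, indent=2, sort_keys=True)
                fh.write("\n")


def run_psa(
    table: ParameterTable,
    posterior: EffectivenessPosterior,
    life_table: LifeTable,
    utility_norms: UtilityNorms,
    settings: Settings | None = None,
    strategies: tuple[StrategySpec, ...] = STRATEGIES,
) -> PSAResult:
    """Run the full probabilistic analysis.

    One vectorised parameter batch of ``settings.n_draws`` joint draws is
    paired row-by-row with the posterior matrix and pushed through all three
    stages for every strategy.  Deterministic given ``settings.seed``.
    """
    settings = settings or Settings()
    if posterior.n_draws != settings.n_draws:
        raise ValueError(
            f"posterior has {posterior.n_draws} draws but settings request "
            f"{settings.n_draws}; parameter draw i is paired with posterior row i"
        )
    rng = np.random.default_rng(settings.seed)
    draw = sample_draw(table, rng, utility_norms, size=settings.n_draws)
    if settings.equalise_severity:
        draw.severity_split_nonfunc = draw.severity_split_func

    n, k = settings.n_draws, len(strategies)
    qalys = np.empty((n, k))
    cost_int = np.empty((n, k))
    costs = {c: np.empty((n, k)) for c in COST_CATEGORIES}
    for j, strategy in enumerate(strategies):
        pi = posterior.column(strategy.id)
        outcome = evaluate_strategy(strategy, draw, pi, life_table, settings)
        qalys[:, j] = outcome.qalys
        cost_int[:, j] = np.broadcast_to(outcome.cost_intervention, (n,))
        for c in COST_CATEGORIES:
            costs[c][:, j] = np.broadcast_to(outcome.costs[c], (n,))
    meta = {
        "n_draws": settings.n_draws,
        "seed": settings.seed,
        "perspective": settings.perspective,
        "scenario": settings.scenario,
        "charge_nonacceptors": settings.charge_nonacceptors,
        "equalise_severity": settings.equalise_severity,
        "h": float(np.asarray(draw.h).flat[0]),
        "cohort_size": float(np.asarray(draw.cohort_size).flat[0]),
    }
    return PSAResult(
        qalys=qalys,
        cost_intervention=cost_int,
        costs=costs,
        labels=tuple(s.label for s in strategies),
        settings=meta,
    )
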