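"""Stage 1: the intervention decision tree.

Converts a promotion strategy plus a parameter draw into (a) the probability
that a household enters the pre-school model in the 'functioning smoke alarm'
state and (b) the expected per-household intervention delivery cost.

Four branches partition the households: (i) already owns a functioning alarm;
(ii) does not own, accepts the offer, and is enabled; (iii) does not own,
accepts, but is not enabled; (iv) does not own and declines.  Branches (i) and
(ii) start stage 2 with a functioning alarm, (iii) and (iv) without one.
Delivery costs fall on the accepting non-owners — branches (ii) and (iii) —
whether or not enablement succeeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterDraw
from .posterior import STRATEGY_LABELS

__all__ = [
    "COMPONENTS",
    "StrategySpec",
    "STRATEGIES",
    "get_strategy",
    "TreeResult",
    "strategy_cost",
    "branch_probabilities",
    "evaluate_tree",
]

#: intervention building blocks: Education, Free/low-cost Equipment, Fitting,
#: Home safety Inspection
COMPONENTS = ("E", "FE", "F", "HI")


@dataclass(frozen=True)
class StrategySpec:
    """One of the seven promotion strategies, as a set of components."""

    id: int
    label: str
    components: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.components - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown intervention component(s): {sorted(unknown)}")
        if self.id == 1 and self.components:
            raise ValueError("usual care must have an empty component set")

    @property
    def is_usual_care(self) -> bool:
        return not self.components


def _make_strategies() -> tuple[StrategySpec, ...]:
    comps = {
        "UC": (),
        "E": ("E",),
        "E+FE": ("E", "FE"),
        "E+FE+HI": ("E", "FE", "HI"),
        "E+FE+F": ("E", "FE", "F"),
        "E+HI": ("E", "HI"),
        "E+FE+F+HI": ("E", "FE", "F", "HI"),
    }
    return tuple(
        StrategySpec(i + 1, label, frozenset(comps[label]))
        for i, label in enumerate(STRATEGY_LABELS)
    )


#: the seven compared strategies, ids 1..7 in reporting order
STRATEGIES = _make_strategies()


def get_strategy(key: int | str) -> StrategySpec:
    """Look up a strategy by 1-based id or label."""
    for s in STRATEGIES:
        if s.id == key or s.label == key:
            return s
    raise KeyError(f"unknown strategy {key!r}; expected 1..7 or one of {STRATEGY_LABELS}")


@dataclass(frozen=True)
class TreeResult:
    """Stage-1 output: starting alarm coverage and delivery cost per household."""

    p_start_functioning: float | np.ndarray
    cost_intervention: float | np.ndarray


def strategy_cost(strategy: StrategySpec, draw: ParameterDraw):
    """Summed component delivery cost of a strategy (GBP per delivered household).

    Monotone non-decreasing under component-set inclusion for non-negative
    component costs; usual care costs nothing.
    """
    total = 0.0
    for comp in COMPONENTS:
        if comp in strategy.components:
            c = draw.component_cost(comp)
            if np.any(np.asarray(c) < 0.0):
                raise ValueError(f"negative delivery cost for component {comp}")
            total = total + c
    return total


def branch_probabilities(draw: ParameterDraw, pi_k):
    """Probabilities of the four tree branches (i)-(iv); they sum to one."""
    p_prev, p_accept = draw.p_prev, draw.p_accept
    pi_k = np.asarray(pi_k)
    owns = p_prev
    enabled = (1.0 - p_prev) * p_accept * pi_k
    accepts_not_enabled = (1.0 - p_prev) * p_accept * (1.0 - pi_k)
    declines = (1.0 - p_prev) * (1.0 - p_accept)
    return owns, enabled, accepts_not_enabled, declines


def evaluate_tree(
    strategy: StrategySpec,
    draw: ParameterDraw,
    pi_k,
    charge_nonacceptors: bool = False,
) -> TreeResult:
    """Run the decision tree for one strategy.

    ``pi_k`` is the enablement probability for the strategy (0 for usual care,
    by definition).  With ``charge_nonacceptors`` the delivery cost falls on
    every offered non-owner rather than only the accepting share.
    """
    pi_k = np.asarray(pi_k, dtype=float)
    if np.any(pi_k < 0.0) or np.any(pi_k > 1.0):
        raise ValueError("pi_k must lie in [0, 1]")
    if strategy.is_usual_care and np.any(pi_k != 0.0):
        raise ValueError("usual care has no intervention effect: pi_k must be 0")
    owns, enabled, _, _ = branch_probabilities(draw, pi_k)
    p_start = owns + enabled
    per_delivery = strategy_cost(strategy, draw)
    reach = 1.0 - draw.p_prev if charge_nonacceptors else (1.0 - draw.p_prev) * draw.p_accept
    cost = reach * per_delivery
    if strategy.is_usual_care:
        cost = np.zeros_like(pi_k) if pi_k.ndim else 0.0
    return TreeResult(p_start_functioning=p_start, cost_intervention=cost)
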