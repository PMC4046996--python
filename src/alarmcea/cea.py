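"""Cost-effectiveness decision analytics.

Operates on a :class:`~alarmcea.psa.PSAResult` (or plain per-strategy means):
incremental analysis with dominance and extended dominance, ICERs, net
monetary benefit, cost-effectiveness acceptability curves, and the expected
value of perfect information at decision and population level.

Frontier construction follows the standard incremental algorithm: strategies
are ordered by effectiveness; any strategy costing at least as much as an
alternative that is no less effective (strictly worse on one axis) is
dominated; among the rest, strategies are removed by extended dominance until
the ICER sequence along the frontier is strictly increasing.  Ties are broken
deterministically: equal effectiveness sorts by ascending cost, equal-cost
equal-effect duplicates collapse onto the earlier index, and NMB ties in CEAC
counting are awarded to the cheaper strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psa import PSAResult

__all__ = [
    "FrontierResult",
    "CEACResult",
    "EVPIResult",
    "mean_outcomes",
    "icer",
    "compute_frontier",
    "nmb",
    "ceac",
    "evpi",
    "population_evpi",
]

FRONTIER = "frontier"
DOMINATED = "dominated"
EXT_DOMINATED = "extendedly_dominated"


def mean_outcomes(psa: PSAResult, perspective: str | None = None) -> pd.DataFrame:
    """Per-strategy mean QALYs and mean total costs, averaged across all draws."""
    if psa.n_draws < 1:
        raise ValueError("empty PSA")
    return psa.mean_outcomes(perspective)


def icer(delta_cost, delta_qaly) -> float:
    """Incremental cost-effectiveness ratio; undefined for zero QALY increments."""
    if np.any(np.asarray(delta_qaly) == 0.0):
        raise ZeroDivisionError(
            "ICER undefined for zero incremental QALYs (a dominance situation)"
        )
    return delta_cost / delta_qaly


@dataclass
class FrontierResult:
    """Dominance statuses plus the incremental chain along the frontier."""

    labels: tuple[str, ...]
    qalys: np.ndarray
    costs: np.ndarray
    status: tuple[str, ...]
    frontier_indices: tuple[int, ...]

    @property
    def n_excluded(self) -> int:
        """Strategies not on the frontier (dominated or extendedly dominated)."""
        return sum(s != FRONTIER for s in self.status)

    @property
    def frontier_labels(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.frontier_indices)

    def table(self) -> pd.DataFrame:
        """Incremental-analysis report (the printed-results layout)."""
        inc_q = {}
        inc_c = {}
        icers = {}
        for prev, cur in zip(self.frontier_indices[:-1], self.frontier_indices[1:]):
            dq = self.qalys[cur] - self.qalys[prev]
            dc = self.costs[cur] - self.costs[prev]
            inc_q[cur], inc_c[cur] = dq, dc
            icers[cur] = dc / dq
        rows = []
        for i, label in enumerate(self.labels):
            rows.append(
                {
                    "strategy": label,
                    "expected_qalys": self.qalys[i],
                    "expected_cost": self.costs[i],
                    "incremental_qalys": inc_q.get(i, np.nan),
                    "incremental_cost": inc_c.get(i, np.nan),
                    "icer": icers.get(i, np.nan),
                    "status": self.status[i],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        with pd.option_context("display.width", 120):
            return self.table().to_string(index=False, float_format=lambda x: f"{x:,.3f}")


def compute_frontier(qalys, costs, labels=None) -> FrontierResult:
    """Dominance / extended-dominance analysis of per-strategy mean outcomes."""
    qalys = np.asarray(qalys, dtype=float)
    costs = np.asarray(costs, dtype=float)
    n = len(qalys)
    if n < 1 or len(costs) != n:
        raise ValueError("need matching non-empty qalys and costs")
    labels = tuple(labels) if labels is not None else tuple(f"S{i + 1}" for i in range(n))

    status = [FRONTIER] * n
    for j in range(n):
        for k in range(n):
            if k == j:
                continue
            better = costs[k] <= costs[j] and qalys[k] >= qalys[j]
            strictly = costs[k] < costs[j] or qalys[k] > qalys[j]
            duplicate = costs[k] == costs[j] and qalys[k] == qalys[j] and k < j
            if better and (strictly or duplicate):
                status[j] = DOMINATED
                break

    candidates = sorted(
        (i for i in range(n) if status[i] == FRONTIER),
        key=lambda i: (qalys[i], costs[i], i),
    )
    # monotone-ICER stack: pop members whose ICER step is not strictly increasing
    stack: list[int] = []
    for i in candidates:
        while stack:
            top = stack[-1]
            step = (costs[i] - costs[top]) / (qalys[i] - qalys[top])
            if len(stack) >= 2:
                prev = stack[-2]
                prev_step = (costs[top] - costs[prev]) / (qalys[top] - qalys[prev])
                if step <= prev_step:
                    status[top] = EXT_DOMINATED
                    stack.pop()
                    continue
            break
        stack.append(i)
    return FrontierResult(
        labels=labels,
        qalys=qalys,
        costs=costs,
        status=tuple(status),
        frontier_indices=tuple(stack),
    )


def nmb(psa: PSAResult, threshold: float, perspective: str | None = None) -> np.ndarray:
    """Per-draw per-strategy net monetary benefit: threshold * QALYs - costs."""
    if threshold < 0.0:
        raise ValueError("threshold must be >= 0")
    return threshold * psa.qalys - psa.total_costs(perspective)


@dataclass
class CEACResult:
    """Probability of each strategy being cost-effective across thresholds."""

    thresholds: np.ndarray
    probabilities: np.ndarray  # (n_thresholds, n_strategies)
    labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.probabilities, columns=list(self.labels))
        frame.insert(0, "threshold", self.thresholds)
        return frame

    def at(self, threshold: float) -> dict:
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        return dict(zip(self.labels, self.probabilities[i]))


def _winners(benefit: np.ndarray, costs: np.ndarray) -> np.ndarray:
    """Index of the cost-effective strategy per draw; NMB ties go to lower cost,
    remaining ties to the lower strategy index."""
    best = benefit.max(axis=1, keepdims=True)
    tied_cost = np.where(benefit == best, costs, np.inf)
    return tied_cost.argmin(axis=1)


def ceac(psa: PSAResult, thresholds, perspective: str | None = None) -> CEACResult:
    """Cost-effectiveness acceptability curves over a threshold grid."""
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    costs = psa.total_costs(perspective)
    probs = np.empty((thresholds.size, psa.n_strategies))
    for i, lam in enumerate(thresholds):
        winners = _winners(lam * psa.qalys - costs, costs)
        probs[i] = np.bincount(winners, minlength=psa.n_strategies) / psa.n_draws
    return CEACResult(thresholds=thresholds, probabilities=probs, labels=psa.labels)


@dataclass
class EVPIResult:
    """Expected value of perfect information at a willingness-to-pay threshold."""

    threshold: float
    per_decision: float
    population: float | None = None
    annual_population: float | None = None
    horizon_years: int | None = None
    discount_rate: float | None = None


def evpi(psa: PSAResult, threshold: float, perspective: str | None = None) -> EVPIResult:
    """Per-decision EVPI: E[max NMB] - max E[NMB]; never negative."""
    benefit = nmb(psa, threshold, perspective)
    value = float(benefit.max(axis=1).mean() - benefit.mean(axis=0).max())
    return EVPIResult(threshold=threshold, per_decision=max(value, 0.0))


def population_evpi(
    per_decision_evpi: float,
    annual_population: float,
    horizon_years: int,
    discount_rate: float = 0.035,
    discounted: bool = True,
) -> float:
    """Scale per-decision EVPI to the population the decision covers.

    Sums the annual affected population over the decision's lifetime (horizon
    years, discounted from year 0 at the model's rate unless ``discounted`` is
    False) and multiplies by the per-decision EVPI.
    """
    if min(per_decision_evpi, annual_population, horizon_years) < 0 or discount_rate < 0:
        raise ValueError("population EVPI inputs must be >= 0")
    t = np.arange(horizon_years)
    weights = (1.0 + discount_rate) ** (-t) if discounted else np.ones_like(t, dtype=float)
    return float(per_decision_evpi * annual_population * weights.sum())
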