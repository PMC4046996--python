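"""Stage 3: the lifetime Markov model (ages 5-99).

Projects the terminal pre-school distribution — (alive never-severe, alive
post-severe, dead) — to age 99 with annual life-table mortality.  The healthy
accrue the age-specific population utility norm; post-severe survivors accrue
the norm minus a lifelong decrement plus an ongoing annual care cost.  All
rewards are valued at cycle start and discounted to birth on the same clock as
the pre-school model (the discount exponent is the age itself).  By default
post-severe survivors face the same mortality as the healthy; an optional
hazard ratio on the draw can impose excess mortality.  The model stops at age
99 inclusive; any remaining survivors contribute nothing further.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import MAX_AGE, LifeTable
from .parameters import COST_CATEGORIES, ParameterDraw

__all__ = ["LIFETIME_START_AGE", "LifetimeResult", "discount_factor", "run_lifetime"]

LIFETIME_START_AGE = 5


def discount_factor(t, r):
    """Present-value factor (1+r)^(-t) for a reward accruing t years from birth."""
    if np.any(np.asarray(r) < 0.0):
        raise ValueError("discount rate must be >= 0")
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be >= 0")
    return (1.0 + r) ** (-t)


def _zero_costs() -> dict:
    return {c: 0.0 for c in COST_CATEGORIES}


@dataclass
class LifetimeResult:
    """Discounted QALYs and costs over ages 5-99, plus undiscounted life-years."""

    qalys: float | np.ndarray
    costs_child: dict = field(default_factory=_zero_costs)
    life_years: float | np.ndarray = 0.0


def run_lifetime(
    start: np.ndarray, draw: ParameterDraw, life_table: LifeTable
) -> LifetimeResult:
    """Run the lifetime projection from a (healthy, post-severe, dead) start."""
    start = np.asarray(start, dtype=float)
    if start.shape[-1] != 3:
        raise ValueError("start distribution must have 3 states")
    if np.any(start < -1e-8) or np.any(np.abs(start.sum(axis=-1) - 1.0) > 1e-8):
        raise ValueError("start distribution must be non-negative and sum to 1")
    life_table.require_ages(LIFETIME_START_AGE, MAX_AGE)

    healthy = start[..., 0].copy()
    severe = start[..., 1].copy()
    norms = draw.utility_norms
    hr = draw.severe_mortality_hr
    result = LifetimeResult(qalys=0.0)
    for age in range(LIFETIME_START_AGE, MAX_AGE + 1):
        u = norms.at(age)
        df = discount_factor(age, draw.r)
        result.qalys = result.qalys + df * (
            healthy * u + severe * (u - draw.du_severe)
        )
        result.costs_child["NHS_PSS"] = (
            result.costs_child["NHS_PSS"] + df * severe * draw.c_severe_annual
        )
        result.life_years = result.life_years + healthy + severe
        q = life_table.q(age)
        q_severe = np.minimum(q * hr, 1.0)
        healthy = healthy * (1.0 - q)
        severe = severe * (1.0 - q_severe)
    return result
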