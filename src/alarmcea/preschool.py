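"""Stage 2: the pre-school Markov cohort model (ages 0-4).

Five joint states track the household alarm and the child's injury history:

0. functioning alarm, child never severely injured
1. no/non-functioning alarm, child never severely injured
2. functioning alarm, child post-severe-injury
3. no/non-functioning alarm, child post-severe-injury
4. dead (absorbing)

Each yearly cycle applies events in a fixed order: (1) a house fire with
probability ``p_fire``; (2) given a fire, a child injury with the
alarm-state-specific probability; (3) given an injury, a severity drawn from
the alarm-state-specific (minor, moderate, severe, fatal) split — fatal moves
the child to dead, severe sets the lifelong post-severe flag; (4) background
mortality from the life table at the child's age; (5) the alarm decays or is
repaired, which determines the *next* cycle's alarm state.  At most one fire
(hence one injury) can occur per cycle by construction.

State-occupancy rewards are valued at cycle start with no half-cycle
correction; event costs are booked in the cycle of the event; a newly severe
child accrues the utility decrement and ongoing annual cost from the event
cycle onward.  A repeat severe injury to an already post-severe child adds
acute costs only.  Everything is an expectation over a unit household and is
written with numpy broadcasting, so a draw may carry scalar parameters or
whole vectorised batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import LifeTable
from .lifetime import discount_factor
from .parameters import COST_CATEGORIES, ParameterDraw
from .tree import TreeResult

__all__ = [
    "STATE_LABELS",
    "PRESCHOOL_CYCLES",
    "PreschoolState",
    "PreschoolResult",
    "step_preschool",
    "run_preschool",
]

STATE_LABELS = (
    "func_never_severe",
    "nonfunc_never_severe",
    "func_post_severe",
    "nonfunc_post_severe",
    "dead",
)
SEVERITY_LABELS = ("minor", "moderate", "severe", "fatal")
PRESCHOOL_CYCLES = 5

_OCC_TOL = 1e-8


def _zero_costs() -> dict:
    return {c: 0.0 for c in COST_CATEGORIES}


@dataclass
class PreschoolState:
    """Occupancy over the five joint states plus the cycle index (child age)."""

    occupancy: np.ndarray
    cycle: int = 0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape[-1] != len(STATE_LABELS):
            raise ValueError(f"occupancy must have {len(STATE_LABELS)} states")
        self.occupancy = occ

    def check(self) -> None:
        occ = self.occupancy
        if np.any(occ < -_OCC_TOL):
            raise ValueError("negative state occupancy")
        if np.any(np.abs(occ.sum(axis=-1) - 1.0) > _OCC_TOL):
            raise ValueError("state occupancy does not sum to 1")


@dataclass
class PreschoolResult:
    """Discounted pre-school QALYs/costs, expected event counts, terminal split.

    Costs are itemised by category and, separately, by whether they scale with
    the number of children per household (``costs_child``: injury consequences)
    or attach to the household itself (``costs_household``: fire attendance and
    property damage).  ``terminal`` is the (alive never-severe, alive
    post-severe, dead) distribution handed to the lifetime model.  ``trace``
    stacks the start-of-cycle occupancies plus the final occupancy.
    """

    qalys: float | np.ndarray
    costs_child: dict = field(default_factory=_zero_costs)
    costs_household: dict = field(default_factory=_zero_costs)
    counts: dict = field(default_factory=dict)
    terminal: np.ndarray | None = None
    trace: np.ndarray | None = None

    def trace_frame(self):
        """Cycle-by-state occupancy trace as a DataFrame (scalar draws only)."""
        import pandas as pd

        if self.trace is None or self.trace.ndim != 2:
            raise ValueError("trace export requires a scalar (non-batched) run")
        frame = pd.DataFrame(self.trace, columns=list(STATE_LABELS))
        frame.insert(0, "cycle", np.arange(len(frame)))
        return frame


def _cycle_quantities(occ: np.ndarray, draw: ParameterDraw, q: float):
    """Expected rewards, costs, counts and the post-cycle occupancy for one cycle."""
    fh, nh, fs, ns, dead = (occ[..., i] for i in range(5))
    pf = draw.p_fire
    p_inj = {"F": draw.p_injury_func, "N": draw.p_injury_nonfunc}
    split = {"F": draw.severity_split_func, "N": draw.severity_split_nonfunc}
    alive = {"F": fh + fs, "N": nh + ns}
    healthy = {"F": fh, "N": nh}
    severe = {"F": fs, "N": ns}

    fires = pf * (alive["F"] + alive["N"])
    counts = {k: 0.0 for k in SEVERITY_LABELS}
    new_severe = 0.0  # healthy -> post-severe flag mass this cycle
    dead_add = 0.0
    surv = {}  # post-event, post-mortality alive masses by alarm state
    for a in ("F", "N"):
        s = split[a]
        m, mo, sv, ft = (s[..., i] for i in range(4))
        inj = pf * p_inj[a]
        counts["minor"] = counts["minor"] + alive[a] * inj * m
        counts["moderate"] = counts["moderate"] + alive[a] * inj * mo
        counts["severe"] = counts["severe"] + alive[a] * inj * sv
        counts["fatal"] = counts["fatal"] + alive[a] * inj * ft
        fatal = inj * ft
        newly_severe = healthy[a] * inj * sv
        new_severe = new_severe + newly_severe
        dead_add = dead_add + alive[a] * (fatal + (1.0 - fatal) * q)
        surv[a] = {
            "healthy": healthy[a] * (1.0 - fatal - inj * sv) * (1.0 - q),
            "severe": (severe[a] * (1.0 - fatal) + newly_severe) * (1.0 - q),
        }
    counts["fires"] = fires

    # alarm decay/repair fixes the next cycle's alarm state
    dd, dr = draw.d_decay, draw.d_repair
    occ_next = np.empty_like(occ)
    occ_next[..., 0] = surv["F"]["healthy"] * (1.0 - dd) + surv["N"]["healthy"] * dr
    occ_next[..., 1] = surv["F"]["healthy"] * dd + surv["N"]["healthy"] * (1.0 - dr)
    occ_next[..., 2] = surv["F"]["severe"] * (1.0 - dd) + surv["N"]["severe"] * dr
    occ_next[..., 3] = surv["F"]["severe"] * dd + surv["N"]["severe"] * (1.0 - dr)
    occ_next[..., 4] = dead + dead_add

    severe_mass = fs + ns + new_severe  # accrues decrement + ongoing cost this cycle
    costs_child = {
        "NHS_PSS": (
            counts["minor"] * draw.c_minor
            + counts["moderate"] * draw.c_moderate
            + counts["severe"] * draw.c_severe_acute
            + severe_mass * draw.c_severe_annual
        ),
        "other_public": 0.0,
        "household": counts["fatal"] * draw.c_fatal_event,
        "productivity": counts["fatal"] * draw.c_fatal_productivity,
    }
    costs_household = {
        "NHS_PSS": 0.0,
        "other_public": fires * draw.c_fire_rescue,
        "household": fires * draw.c_property,
        "productivity": 0.0,
    }
    return occ_next, severe_mass, costs_child, costs_household, counts


def step_preschool(state: PreschoolState, draw: ParameterDraw, life_table: LifeTable):
    """Advance one pre-school cycle.

    Returns ``(next_state, cycle_qalys, cycle_costs, cycle_counts)`` where the
    QALYs/costs are undiscounted within-cycle expectations and ``cycle_costs``
    maps category -> (child-scaled, household-level) amounts.
    """
    state.check()
    age = state.cycle
    life_table.require_ages(0, PRESCHOOL_CYCLES - 1)
    q = life_table.q(age)
    occ = state.occupancy
    occ_next, severe_mass, costs_child, costs_household, counts = _cycle_quantities(
        occ, draw, q
    )
    u = draw.utility_norms.at(age)
    alive_start = 1.0 - occ[..., 4]
    qalys = alive_start * u - draw.du_severe * severe_mass
    costs = {c: (costs_child[c], costs_household[c]) for c in COST_CATEGORIES}
    return PreschoolState(occ_next, cycle=age + 1), qalys, costs, counts


def run_preschool(
    tree: TreeResult, draw: ParameterDraw, life_table: LifeTable
) -> PreschoolResult:
    """Run the five pre-school cycles from the stage-1 starting distribution."""
    p0 = np.asarray(tree.p_start_functioning, dtype=float)
    if np.any(p0 < 0.0) or np.any(p0 > 1.0):
        raise ValueError("p_start_functioning must lie in [0, 1]")
    life_table.require_ages(0, PRESCHOOL_CYCLES - 1)
    occ = np.zeros(np.shape(p0) + (len(STATE_LABELS),))
    occ[..., 0] = p0
    occ[..., 1] = 1.0 - p0
    state = PreschoolState(occ, cycle=0)

    result = PreschoolResult(qalys=0.0)
    result.counts = {k: 0.0 for k in (*SEVERITY_LABELS, "fires")}
    trace = [state.occupancy.copy()]
    for t in range(PRESCHOOL_CYCLES):
        df = discount_factor(t, draw.r)
        state, qalys, costs, counts = step_preschool(state, draw, life_table)
        result.qalys = result.qalys + df * qalys
        for c in COST_CATEGORIES:
            child, household = costs[c]
            result.costs_child[c] = result.costs_child[c] + df * child
            result.costs_household[c] = result.costs_household[c] + df * household
        for k, v in counts.items():
            result.counts[k] = result.counts[k] + v
        trace.append(state.occupancy.copy())
    state.check()

    occ = state.occupancy
    terminal = np.stack(
        [occ[..., 0] + occ[..., 1], occ[..., 2] + occ[..., 3], occ[..., 4]], axis=-1
    )
    result.terminal = terminal
    result.trace = np.stack(trace, axis=0)
    return result
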