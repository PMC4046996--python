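"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force — per-household stochastic
microsimulation for the cohort expectations, and exhaustive pairwise/segment
enumeration for the cost-effectiveness frontier — sharing no code path with
the implementations they check.
"""

from __future__ import annotations

import numpy as np

FRONTIER, DOMINATED, EXT = "frontier", "dominated", "extendedly_dominated"


def frontier_oracle(qalys, costs) -> list[str]:
    """Brute-force dominance classification.

    A strategy is dominated if some other strategy is weakly better on both
    axes and strictly better on one (equal-equal duplicates collapse onto the
    earlier index); a non-dominated strategy is extendedly dominated if a
    convex blend of two other non-dominated strategies achieves its
    effectiveness at lower cost.
    """
    qalys = np.asarray(qalys, float)
    costs = np.asarray(costs, float)
    n = len(qalys)
    status = [FRONTIER] * n
    for j in range(n):
        for k in range(n):
            if k == j:
                continue
            weakly = costs[k] <= costs[j] and qalys[k] >= qalys[j]
            strictly = costs[k] < costs[j] or qalys[k] > qalys[j]
            dup = costs[k] == costs[j] and qalys[k] == qalys[j] and k < j
            if weakly and (strictly or dup):
                status[j] = DOMINATED
                break
    nd = [i for i in range(n) if status[i] == FRONTIER]
    for j in nd:
        for k in nd:
            for l in nd:
                if qalys[k] < qalys[j] < qalys[l]:
                    a = (qalys[j] - qalys[k]) / (qalys[l] - qalys[k])
                    blend = costs[k] + a * (costs[l] - costs[k])
                    if blend < costs[j]:
                        status[j] = EXT
    return status


def frontier_choice_by_icer(frontier_result, threshold: float) -> int:
    """Decision rule on the ICER chain: adopt the most effective frontier
    strategy whose incremental step is worth paying at the threshold."""
    chain = list(frontier_result.frontier_indices)
    choice = chain[0]
    for prev, cur in zip(chain[:-1], chain[1:]):
        step = (frontier_result.costs[cur] - frontier_result.costs[prev]) / (
            frontier_result.qalys[cur] - frontier_result.qalys[prev]
        )
        if step <= threshold:
            choice = cur
    return choice


def microsimulate(strategy, draw, pi: float, life_table, n_households: int, rng):
    """Stochastic per-household simulation with the same event rules as the
    cohort model (one child per household; ``h`` is ignored).

    Returns per-household sample arrays so callers can form Monte-Carlo
    standard errors: discounted QALYs, discounted costs by category (child and
    household components combined), intervention cost, and event counts.
    """
    n = n_households
    norms = draw.utility_norms
    r = draw.r

    prev = rng.random(n) < draw.p_prev
    accept = rng.random(n) < draw.p_accept
    enabled = rng.random(n) < pi
    func = prev | (~prev & accept & enabled)
    per_delivery = sum(draw.component_cost(c) for c in sorted(strategy.components))
    cost_int = np.where(~prev & accept, float(per_delivery), 0.0)
    if strategy.is_usual_care:
        cost_int[:] = 0.0

    alive = np.ones(n, bool)
    severe = np.zeros(n, bool)
    qalys = np.zeros(n)
    costs = {c: np.zeros(n) for c in ("NHS_PSS", "other_public", "household", "productivity")}
    counts = {c: np.zeros(n) for c in ("minor", "moderate", "severe", "fatal", "fires")}
    split_f = np.asarray(draw.severity_split_func, float)
    split_n = np.asarray(draw.severity_split_nonfunc, float)

    for t in range(5):
        df = (1.0 + r) ** (-t)
        u = norms.at(t)
        q = life_table.q(t)
        start_alive = alive.copy()
        start_severe = severe & alive
        fire = start_alive & (rng.random(n) < draw.p_fire)
        p_inj = np.where(func, draw.p_injury_func, draw.p_injury_nonfunc)
        injured = fire & (rng.random(n) < p_inj)
        cdf = np.where(func[:, None], split_f[None, :], split_n[None, :]).cumsum(axis=1)
        cat = (rng.random(n)[:, None] > cdf).sum(axis=1)
        minor = injured & (cat == 0)
        moderate = injured & (cat == 1)
        severe_event = injured & (cat == 2)
        fatal = injured & (cat == 3)
        new_severe = severe_event & ~start_severe
        du_mass = start_severe | new_severe
        severe |= severe_event
        alive &= ~fatal
        alive &= ~(alive & (rng.random(n) < q))
        flip = rng.random(n)
        func = np.where(func, flip >= draw.d_decay, flip < draw.d_repair)

        qalys += df * (start_alive * u - draw.du_severe * du_mass)
        costs["NHS_PSS"] += df * (
            minor * draw.c_minor
            + moderate * draw.c_moderate
            + severe_event * draw.c_severe_acute
            + du_mass * draw.c_severe_annual
        )
        costs["household"] += df * (fatal * draw.c_fatal_event + fire * draw.c_property)
        costs["productivity"] += df * fatal * draw.c_fatal_productivity
        costs["other_public"] += df * fire * draw.c_fire_rescue
        for name, mask in (
            ("minor", minor), ("moderate", moderate), ("severe", severe_event),
            ("fatal", fatal), ("fires", fire),
        ):
            counts[name] += mask

    for age in range(5, life_table.max_age + 1):
        df = (1.0 + r) ** (-age)
        u = norms.at(age)
        qalys += df * (alive * u - (alive & severe) * draw.du_severe)
        costs["NHS_PSS"] += df * (alive & severe) * draw.c_severe_annual
        q = life_table.q(age)
        q_ind = np.where(severe, min(q * draw.severe_mortality_hr, 1.0), q)
        alive &= ~(alive & (rng.random(n) < q_ind))

    return {"qalys": qalys, "costs": costs, "cost_intervention": cost_int, "counts": counts}
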