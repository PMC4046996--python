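"""Shared fixtures: null baseline draws for closed-form checks, the synthetic
default inputs, degenerate (uncertainty-free) variants, and hand-built PSA
matrices for the decision-analytic tests."""

from __future__ import annotations

import numpy as np
import pytest

from alarmcea import (
    LifeTable,
    ParameterDraw,
    PSAResult,
    UtilityNorms,
    default_inputs,
    default_parameter_table,
    default_utility_norms,
    synthetic_life_table,
)
from alarmcea.demography import MAX_AGE
from alarmcea.parameters import DistributionSpec, ParameterTable


def constant_norms(u: float = 1.0) -> UtilityNorms:
    return UtilityNorms(np.array([0]), np.array([MAX_AGE]), np.array([u]))


def flat_life_table(q: float = 0.0) -> LifeTable:
    return LifeTable(np.full(MAX_AGE + 1, q))


def make_draw(**overrides) -> ParameterDraw:
    """A null-baseline draw (no fires, no discounting, unit utility) that
    individual tests override field by field for closed-form arithmetic."""
    fields = dict(
        p_prev=0.8,
        p_accept=0.9,
        d_decay=0.1,
        d_repair=0.1,
        p_fire=0.0,
        p_injury_func=0.6,
        p_injury_nonfunc=0.91,
        severity_split_func=np.array([0.80, 0.15, 0.03, 0.02]),
        severity_split_nonfunc=np.array([0.70, 0.20, 0.06, 0.04]),
        c_E=20.0,
        c_FE=30.0,
        c_F=40.0,
        c_HI=50.0,
        c_minor=250.0,
        c_moderate=2500.0,
        c_severe_acute=60000.0,
        c_severe_annual=5000.0,
        c_fatal_event=1500.0,
        c_fatal_productivity=600000.0,
        c_fire_rescue=2500.0,
        c_property=8800.0,
        du_severe=0.0,
        r=0.0,
        h=1.0,
        cohort_size=100000.0,
        utility_norms=constant_norms(),
    )
    fields.update(overrides)
    draw = ParameterDraw(**fields)
    draw.validate()
    return draw


def degenerate_table(table: ParameterTable | None = None) -> ParameterTable:
    """Every distribution replaced by a fixed spec at its closed-form mean."""
    table = table or default_parameter_table()
    out = table
    for name in table.names():
        mean = table[name].spec.mean()
        values = tuple(np.atleast_1d(np.asarray(mean, float)))
        out = out.replace_spec(name, DistributionSpec("fixed", values))
    return out


def make_psa(qalys, costs, labels=None, intervention=None) -> PSAResult:
    """A PSAResult from plain (n_draws, n_strategies) arrays, costs booked as
    NHS/PSS so every perspective sees them."""
    qalys = np.asarray(qalys, float)
    costs = np.asarray(costs, float)
    n, k = qalys.shape
    zeros = np.zeros_like(qalys)
    return PSAResult(
        qalys=qalys,
        cost_intervention=zeros if intervention is None else np.asarray(intervention, float),
        costs={
            "NHS_PSS": costs,
            "other_public": zeros.copy(),
            "household": zeros.copy(),
            "productivity": zeros.copy(),
        },
        labels=tuple(labels) if labels else tuple(f"S{i + 1}" for i in range(k)),
        settings={"perspective": "public_sector", "n_draws": n},
    )


@pytest.fixture(scope="session")
def fixture_table() -> ParameterTable:
    return default_parameter_table()


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return synthetic_life_table()


@pytest.fixture(scope="session")
def norms() -> UtilityNorms:
    return default_utility_norms()


@pytest.fixture(scope="session")
def small_inputs():
    return default_inputs(n_draws=64, seed=11)
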