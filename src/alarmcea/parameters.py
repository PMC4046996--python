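"""Uncertain model inputs: distribution specifications, the parameter table,
and sampled parameter draws.

Every quantity the model is uncertain about is declared once, in a
:class:`ParameterTable`, as a named :class:`DistributionSpec` with a cost-category
tag and a source note.  Probabilistic sensitivity analysis then repeatedly calls
:func:`sample_draw` to obtain a :class:`ParameterDraw` — one joint realisation of
all inputs — which is what every model stage consumes.  All sampling goes through
a single ``numpy.random.Generator`` threaded explicitly through the call, so a
seed fully determines an analysis.

Supported distribution families and their hyperparameters:

=============  =======================================  =====================
family         hyperparameters                          support
=============  =======================================  =====================
``fixed``      the value(s); a vector fixes a           as given
               probability split
``beta``       alpha, beta (both > 0)                   [0, 1]
``gamma``      shape, scale (both > 0)                  (0, inf)
``lognormal``  mu, sigma of log (sigma >= 0)            (0, inf)
``normal``     mean, sd (sd >= 0)                       (-inf, inf)
``dirichlet``  k >= 2 positive concentrations           the k-simplex
=============  =======================================  =====================
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .demography import UtilityNorms

__all__ = [
    "CATEGORIES",
    "COST_CATEGORIES",
    "REQUIRED_PARAMETERS",
    "ParameterError",
    "DistributionSpec",
    "ParameterEntry",
    "ParameterTable",
    "ParameterDraw",
    "load_parameter_table",
    "sample_draw",
]

#: valid cost-category tags for a parameter-table row
CATEGORIES = ("none", "NHS_PSS", "other_public", "household", "productivity")
#: categories that carry money (everything except "none")
COST_CATEGORIES = ("NHS_PSS", "other_public", "household", "productivity")


class ParameterError(ValueError):
    """Raised for invalid distribution specs, incomplete tables or bad draws."""


@dataclass(frozen=True)
class DistributionSpec:
    """A distribution family plus hyperparameters for one uncertain input."""

    family: str
    hyperparameters: tuple[float, ...]
    note: str = ""

    # expected hyperparameter count per family (None = variable arity)
    _ARITY = {
        "fixed": None,
        "beta": 2,
        "gamma": 2,
        "lognormal": 2,
        "normal": 2,
        "dirichlet": None,
    }

    def __post_init__(self) -> None:
        if self.family not in self._ARITY:
            raise ParameterError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {sorted(self._ARITY)}"
            )
        hp = tuple(float(x) for x in self.hyperparameters)
        object.__setattr__(self, "hyperparameters", hp)
        arity = self._ARITY[self.family]
        if arity is not None and len(hp) != arity:
            raise ParameterError(
                f"{self.family} distribution requires {arity} hyperparameters, "
                f"got {len(hp)}: {hp}"
            )
        if self.family == "fixed" and len(hp) < 1:
            raise ParameterError("fixed distribution requires at least one value")
        if self.family == "dirichlet":
            if len(hp) < 2:
                raise ParameterError("dirichlet requires at least 2 concentrations")
            if any(a <= 0 for a in hp):
                raise ParameterError(f"dirichlet concentrations must be > 0: {hp}")
        if self.family in ("beta", "gamma") and any(a <= 0 for a in hp):
            raise ParameterError(f"{self.family} hyperparameters must be > 0: {hp}")
        if self.family in ("lognormal", "normal") and hp[1] < 0:
            raise ParameterError(f"{self.family} scale must be >= 0: {hp}")

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed"

    @property
    def is_vector(self) -> bool:
        """True when sampling yields a probability vector rather than a scalar."""
        return self.family == "dirichlet" or (
            self.family == "fixed" and len(self.hyperparameters) > 1
        )

    def mean(self):
        """Closed-form mean (a vector for dirichlet / vector-fixed specs)."""
        hp = self.hyperparameters
        if self.family == "fixed":
            return hp[0] if len(hp) == 1 else np.asarray(hp)
        if self.family == "beta":
            return hp[0] / (hp[0] + hp[1])
        if self.family == "gamma":
            return hp[0] * hp[1]
        if self.family == "lognormal":
            return float(np.exp(hp[0] + hp[1] ** 2 / 2.0))
        if self.family == "normal":
            return hp[0]
        alpha = np.asarray(hp)
        return alpha / alpha.sum()

    def variance(self):
        """Closed-form variance (vector of marginal variances for dirichlet)."""
        hp = self.hyperparameters
        if self.family == "fixed":
            return 0.0 if len(hp) == 1 else np.zeros(len(hp))
        if self.family == "beta":
            a, b = hp
            return a * b / ((a + b) ** 2 * (a + b + 1.0))
        if self.family == "gamma":
            return hp[0] * hp[1] ** 2
        if self.family == "lognormal":
            mu, sig = hp
            return float((np.exp(sig**2) - 1.0) * np.exp(2 * mu + sig**2))
        if self.family == "normal":
            return hp[1] ** 2
        alpha = np.asarray(hp)
        a0 = alpha.sum()
        p = alpha / a0
        return p * (1.0 - p) / (a0 + 1.0)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution; ``size=None`` returns a single realisation."""
        hp = self.hyperparameters
        if self.family == "fixed":
            if len(hp) == 1:
                return hp[0] if size is None else np.full(size, hp[0])
            vec = np.asarray(hp)
            return vec.copy() if size is None else np.tile(vec, (size, 1))
        if self.family == "beta":
            return rng.beta(hp[0], hp[1], size=size)
        if self.family == "gamma":
            return rng.gamma(hp[0], hp[1], size=size)
        if self.family == "lognormal":
            return rng.lognormal(hp[0], hp[1], size=size)
        if self.family == "normal":
            return rng.normal(hp[0], hp[1], size=size)
        return rng.dirichlet(hp, size=size)


@dataclass(frozen=True)
class ParameterEntry:
    """One parameter-table row: a distribution, a cost category and a source note."""

    spec: DistributionSpec
    category: str = "none"
    source: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ParameterError(
                f"unknown cost category {self.category!r}; expected one of {CATEGORIES}"
            )


#: every symbol the downstream model stages read from a draw, with a short meaning
REQUIRED_PARAMETERS: Mapping[str, str] = {
    "p_prev": "probability a household already has a functioning alarm",
    "p_accept": "probability of accepting an offered intervention",
    "d_decay": "annual probability alarm functioning -> non-functioning",
    "d_repair": "annual probability alarm non-functioning -> functioning",
    "p_fire": "annual probability of a house fire",
    "p_injury_func": "P(child injury | fire) with a functioning alarm",
    "p_injury_nonfunc": "P(child injury | fire) without a functioning alarm",
    "severity_split_func": "P(minor, moderate, severe, fatal | injury), functioning",
    "severity_split_nonfunc": "P(minor, moderate, severe, fatal | injury), non-functioning",
    "c_E": "delivery cost of the education component (GBP/household)",
    "c_FE": "delivery cost of free/low-cost equipment (GBP/household)",
    "c_F": "delivery cost of equipment fitting (GBP/household)",
    "c_HI": "delivery cost of a home safety inspection (GBP/household)",
    "c_minor": "acute cost of a minor injury (GBP)",
    "c_moderate": "acute cost of a moderate injury (GBP)",
    "c_severe_acute": "acute cost of a severe injury (GBP)",
    "c_severe_annual": "ongoing annual cost of a severely injured survivor (GBP)",
    "c_fatal_event": "cost of a fatality: coroner, autopsy (GBP)",
    "c_fatal_productivity": "lost lifetime productivity after a fatality (GBP)",
    "c_fire_rescue": "fire & rescue attendance cost per fire (GBP)",
    "c_property": "property damage per fire (GBP)",
    "du_severe": "lifelong utility decrement after a severe injury",
    "r": "annual discount rate on costs and health effects",
    "h": "children under 5 per household",
    "cohort_size": "cohort size used for reporting scale",
}

_PROBABILITY_NAMES = (
    "p_prev",
    "p_accept",
    "d_decay",
    "d_repair",
    "p_fire",
    "p_injury_func",
    "p_injury_nonfunc",
)
_COST_NAMES = (
    "c_E",
    "c_FE",
    "c_F",
    "c_HI",
    "c_minor",
    "c_moderate",
    "c_severe_acute",
    "c_severe_annual",
    "c_fatal_event",
    "c_fatal_productivity",
    "c_fire_rescue",
    "c_property",
)


class ParameterTable:
    """Named uncertain-parameter specs keyed by the symbols the model reads.

    Behaves like a read-only mapping of name -> :class:`ParameterEntry`.  Use
    :meth:`override` to produce a copy with some parameters pinned to fixed
    values (how scenario analyses are expressed) and :meth:`to_csv` /
    :func:`load_parameter_table` for the on-disk CSV form.
    """

    def __init__(self, entries: Mapping[str, ParameterEntry]):
        self.entries = dict(entries)

    def __getitem__(self, name: str) -> ParameterEntry:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterTable) and self.entries == other.entries

    def names(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def validate_complete(self) -> None:
        """Raise :class:`ParameterError` naming the first required symbol absent."""
        for name in REQUIRED_PARAMETERS:
            if name not in self.entries:
                raise ParameterError(f"missing parameter: {name}")

    def override(self, values: Mapping[str, float] | None = None, **kw: float) -> "ParameterTable":
        """Copy of the table with the given parameters pinned to fixed values."""
        merged = dict(values or {})
        merged.update(kw)
        entries = dict(self.entries)
        for name, value in merged.items():
            if name not in entries:
                raise ParameterError(f"cannot override unknown parameter: {name}")
            old = entries[name]
            vals = tuple(np.atleast_1d(np.asarray(value, dtype=float)))
            entries[name] = replace(
                old, spec=DistributionSpec("fixed", vals, note="scenario override")
            )
        return ParameterTable(entries)

    def replace_spec(self, name: str, spec: DistributionSpec) -> "ParameterTable":
        entries = dict(self.entries)
        if name not in entries:
            raise ParameterError(f"cannot replace unknown parameter: {name}")
        entries[name] = replace(entries[name], spec=spec)
        return ParameterTable(entries)

    # ------------------------------------------------------------------ I/O
    _HEADER = ("name", "family", "hyperparameters", "category", "source")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(self._HEADER)
            for name, entry in self.entries.items():
                writer.writerow(
                    [
                        name,
                        entry.spec.family,
                        ";".join(f"{x:.17g}" for x in entry.spec.hyperparameters),
                        entry.category,
                        entry.source,
                    ]
                )

    @classmethod
    def from_csv(cls, path) -> "ParameterTable":
        entries: dict[str, ParameterEntry] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or tuple(h.strip() for h in header) != cls._HEADER:
                raise ParameterError(
                    f"bad parameter table header in {path}: expected {cls._HEADER}"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not cell.strip() for cell in row):
                    continue
                if len(row) != len(cls._HEADER):
                    raise ParameterError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
                name, family, hypers, category, source = (cell.strip() for cell in row)
                try:
                    hp = tuple(float(x) for x in hypers.split(";") if x.strip())
                    spec = DistributionSpec(family, hp)
                except (ValueError, ParameterError) as exc:
                    raise ParameterError(f"{path}:{lineno} (parameter {name!r}): {exc}") from exc
                entries[name] = ParameterEntry(spec, category, source)
        table = cls(entries)
        table.validate_complete()
        return table


def load_parameter_table(path) -> ParameterTable:
    """Read a parameter table CSV and verify it covers every required symbol."""
    return ParameterTable.from_csv(path)


@dataclass
class ParameterDraw:
    """One joint realisation of every model input.

    Fields are scalars for a single draw, or 1-d arrays (length ``n_draws``) for
    a vectorised batch of draws; severity splits have a trailing axis of length
    4 ordered (minor, moderate, severe, fatal).  All model stages are written
    with numpy broadcasting so that either form runs through unchanged.
    """

    p_prev: float | np.ndarray
    p_accept: float | np.ndarray
    d_decay: float | np.ndarray
    d_repair: float | np.ndarray
    p_fire: float | np.ndarray
    p_injury_func: float | np.ndarray
    p_injury_nonfunc: float | np.ndarray
    severity_split_func: np.ndarray
    severity_split_nonfunc: np.ndarray
    c_E: float | np.ndarray
    c_FE: float | np.ndarray
    c_F: float | np.ndarray
    c_HI: float | np.ndarray
    c_minor: float | np.ndarray
    c_moderate: float | np.ndarray
    c_severe_acute: float | np.ndarray
    c_severe_annual: float | np.ndarray
    c_fatal_event: float | np.ndarray
    c_fatal_productivity: float | np.ndarray
    c_fire_rescue: float | np.ndarray
    c_property: float | np.ndarray
    du_severe: float | np.ndarray
    r: float
    h: float
    cohort_size: float
    utility_norms: UtilityNorms = field(repr=False, default=None)
    severe_mortality_hr: float = 1.0

    def component_cost(self, component: str):
        return {"E": self.c_E, "FE": self.c_FE, "F": self.c_F, "HI": self.c_HI}[component]

    def validate(self) -> None:
        for name in _PROBABILITY_NAMES + ("du_severe",):
            value = np.asarray(getattr(self, name))
            if np.any(value < 0.0) or np.any(value > 1.0):
                raise ParameterError(f"sampled {name} outside [0, 1]")
        for name in ("severity_split_func", "severity_split_nonfunc"):
            split = np.asarray(getattr(self, name))
            if split.shape[-1] != 4:
                raise ParameterError(f"{name} must have 4 components")
            if np.any(split < 0.0):
                raise ParameterError(f"{name} has negative components")
            if np.any(np.abs(split.sum(axis=-1) - 1.0) > 1e-12):
                raise ParameterError(f"{name} does not sum to 1")
        for name in _COST_NAMES:
            if np.any(np.asarray(getattr(self, name)) < 0.0):
                raise ParameterError(f"sampled {name} is negative")
        if np.any(np.asarray(self.r) < 0.0):
            raise ParameterError("discount rate r must be >= 0")
        if np.any(np.asarray(self.h) < 1.0):
            raise ParameterError("children per household h must be >= 1")
        if self.utility_norms is not None:
            u_min = self.utility_norms.min_utility
            if np.any(np.asarray(self.du_severe) > u_min + 1e-12):
                raise ParameterError(
                    f"du_severe exceeds the minimum age-specific utility norm ({u_min})"
                )
        if np.any(np.asarray(self.severe_mortality_hr) < 0.0):
            raise ParameterError("severe_mortality_hr must be >= 0")


def sample_draw(
    table: ParameterTable,
    rng: np.random.Generator,
    utility_norms: UtilityNorms,
    size: int | None = None,
) -> ParameterDraw:
    """Sample one :class:`ParameterDraw` (or a vectorised batch of ``size``).

    Fixed-family parameters come back exactly; every sampled value is checked
    against its declared support, so mis-specified hyperparameters fail loudly
    rather than silently corrupting a run.  Identical generator state gives
    bitwise-identical draws.
    """
    table.validate_complete()
    values: dict[str, object] = {}
    for name in REQUIRED_PARAMETERS:
        spec = table[name].spec
        if name in ("severity_split_func", "severity_split_nonfunc"):
            if not spec.is_vector or (spec.family == "fixed" and len(spec.hyperparameters) != 4) or (
                spec.family == "dirichlet" and len(spec.hyperparameters) != 4
            ):
                raise ParameterError(
                    f"{name} must be a 4-component dirichlet or fixed vector"
                )
        values[name] = spec.sample(rng, size=size)
    opt_hr = 1.0
    if "severe_mortality_hr" in table:
        opt_hr = table["severe_mortality_hr"].spec.sample(rng, size=size)
    draw = ParameterDraw(
        **{k: values[k] for k in REQUIRED_PARAMETERS},  # type: ignore[arg-type]
        utility_norms=utility_norms,
        severe_mortality_hr=opt_hr,
    )
    # r, h, cohort_size steer discounting/scaling; insist they are scalar-valued
    for name in ("r", "h", "cohort_size"):
        value = np.asarray(values[name])
        if value.ndim and not np.all(value == value.flat[0]):
            raise ParameterError(f"{name} must be a fixed (non-varying) parameter")
        setattr(draw, name, float(value.flat[0]) if value.ndim else float(value))
    draw.validate()
    return draw
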