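"""Life tables and age-specific utility norms.

The cohort is followed from birth to age 99: 5 pre-school cycles (ages 0-4)
and 95 long-term cycles (ages 5-99).  Background mortality comes from an
annual life table (age, qx) and quality-of-life weights from population
utility norms given as a piecewise-constant step function over age bands.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

__all__ = ["LifeTable", "UtilityNorms", "MAX_AGE"]

#: last modelled age (inclusive); survivors beyond it contribute nothing
MAX_AGE = 99


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``qx`` indexed by completed age 0..99."""

    qx: np.ndarray

    def __post_init__(self) -> None:
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "qx", qx)
        if qx.ndim != 1:
            raise ValueError("life table qx must be one-dimensional")
        if np.any(qx < 0.0) or np.any(qx > 1.0):
            raise ValueError("life table qx values must lie in [0, 1]")

    @property
    def max_age(self) -> int:
        return len(self.qx) - 1

    def q(self, age: int) -> float:
        if not 0 <= age <= self.max_age:
            raise ValueError(f"life table does not cover age {age}")
        return float(self.qx[age])

    def require_ages(self, lo: int, hi: int) -> None:
        if lo < 0 or hi > self.max_age:
            raise ValueError(f"life table missing ages {lo}-{hi}")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["age", "qx"])
            for age, q in enumerate(self.qx):
                writer.writerow([age, f"{q:.17g}"])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        ages, qs = [], []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != ["age", "qx"]:
                raise ValueError(f"bad life table header in {path}: expected age,qx")
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                ages.append(int(row[0]))
                qs.append(float(row[1]))
        if not ages:
            raise ValueError(f"life table {path} is empty")
        if ages != list(range(len(ages))):
            raise ValueError(f"life table {path} must list contiguous ages from 0")
        return cls(np.asarray(qs))


@dataclass(frozen=True)
class UtilityNorms:
    """Population quality-of-life norms as a step function over age bands.

    Bands are (age_lo, age_hi) inclusive and must tile 0..99 contiguously;
    utilities lie in [0, 1].
    """

    age_lo: np.ndarray
    age_hi: np.ndarray
    utility: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.age_lo, dtype=int)
        hi = np.asarray(self.age_hi, dtype=int)
        u = np.asarray(self.utility, dtype=float)
        object.__setattr__(self, "age_lo", lo)
        object.__setattr__(self, "age_hi", hi)
        object.__setattr__(self, "utility", u)
        if not (len(lo) == len(hi) == len(u)) or len(lo) == 0:
            raise ValueError("utility norms need matching non-empty band arrays")
        if np.any(u < 0.0) or np.any(u > 1.0):
            raise ValueError("utility norms must lie in [0, 1]")
        if lo[0] != 0 or hi[-1] < MAX_AGE:
            raise ValueError(f"utility norms must cover ages 0-{MAX_AGE}")
        if np.any(lo[1:] != hi[:-1] + 1) or np.any(hi < lo):
            raise ValueError("utility norm age bands must be contiguous and ordered")
        # dense per-age lookup for fast access
        dense = np.empty(int(hi[-1]) + 1)
        for a, b, val in zip(lo, hi, u):
            dense[a : b + 1] = val
        object.__setattr__(self, "_by_age", dense)

    @property
    def min_utility(self) -> float:
        return float(self.utility.min())

    def at(self, age: int) -> float:
        if not 0 <= age < len(self._by_age):
            raise ValueError(f"utility norms do not cover age {age}")
        return float(self._by_age[age])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["age_lo", "age_hi", "utility"])
            for a, b, u in zip(self.age_lo, self.age_hi, self.utility):
                writer.writerow([a, b, f"{u:.17g}"])

    @classmethod
    def from_csv(cls, path) -> "UtilityNorms":
        lo, hi, u = [], [], []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != ["age_lo", "age_hi", "utility"]:
                raise ValueError(f"bad utility norms header in {path}")
            for row in reader:
                if not row or all(not c.strip() for c in row):
                    continue
                lo.append(int(row[0]))
                hi.append(int(row[1]))
                u.append(float(row[2]))
        if not lo:
            raise ValueError(f"utility norms {path} is empty")
        return cls(np.asarray(lo), np.asarray(hi), np.asarray(u))
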