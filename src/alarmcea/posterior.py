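"""Intervention-effectiveness posterior draws.

The effectiveness of the seven smoke-alarm promotion strategies comes from a
mixed-treatment-comparison (network meta-analysis) synthesis whose MCMC output
is consumed as a matrix of posterior draws: one row per draw, one column per
strategy, each entry pi_k being the probability that a household which did not
own a functioning alarm and accepted the offer ends up an enabled
functioning-alarm household under strategy k.  Usual care has no intervention
effect beyond baseline prevalence, so its column is identically zero.

Because the original CODA samples are not distributed, the package emulates
them: correlated multivariate-normal draws of log-odds ratios for the six
active strategies, mapped through the inverse logit against a baseline
log-odds.  Means increase with intervention complexity (number of components),
reflecting the synthesis finding that more multifaceted interventions are more
likely to increase functioning-alarm possession.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "STRATEGY_LABELS",
    "EffectivenessPosterior",
    "generate_effectiveness_posterior",
    "read_posterior",
    "write_posterior",
]

#: the seven strategies, in the fixed column/reporting order (ids 1..7)
STRATEGY_LABELS = ("UC", "E", "E+FE", "E+FE+HI", "E+FE+F", "E+HI", "E+FE+F+HI")


@dataclass(frozen=True)
class EffectivenessPosterior:
    """Posterior draws of enablement probabilities, one column per strategy."""

    draws: np.ndarray
    note: str = ""
    labels: tuple[str, ...] = field(default=STRATEGY_LABELS)

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", draws)
        if draws.ndim != 2 or draws.shape[1] != len(self.labels):
            raise ValueError(
                f"posterior draws must be (n_draws, {len(self.labels)}); got {draws.shape}"
            )
        if draws.shape[0] == 0:
            raise ValueError("no draws")
        if np.any(draws < 0.0) or np.any(draws > 1.0):
            raise ValueError("posterior draws must lie in [0, 1]")
        if np.any(draws[:, 0] != 0.0):
            raise ValueError("usual-care column must be identically zero")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def column(self, strategy_id: int) -> np.ndarray:
        """Draws for the 1-based strategy id."""
        return self.draws[:, strategy_id - 1]


def generate_effectiveness_posterior(
    mean_log_or,
    sd_log_or,
    correlation,
    baseline_logodds: float,
    n_draws: int = 5000,
    rng: np.random.Generator | int | None = None,
) -> EffectivenessPosterior:
    """Emulate MCMC posterior draws of strategy effectiveness.

    Parameters
    ----------
    mean_log_or, sd_log_or
        Length-6 arrays of posterior means / sds of the log-odds ratios for the
        six active strategies (columns 2..7, order of ``STRATEGY_LABELS[1:]``).
    correlation
        6x6 positive-definite correlation matrix between the log-odds ratios.
    baseline_logodds
        Log-odds of enablement that the ratios act on; ``pi_k`` is
        ``expit(baseline_logodds + log_or_k)``.
    n_draws
        Number of posterior rows (5,000 by default, matching the number of
        Monte-Carlo simulations the model is run with).
    rng
        Seed or ``numpy.random.Generator``.
    """
    mean = np.asarray(mean_log_or, dtype=float)
    sd = np.asarray(sd_log_or, dtype=float)
    corr = np.asarray(correlation, dtype=float)
    k = len(STRATEGY_LABELS) - 1
    if mean.shape != (k,) or sd.shape != (k,):
        raise ValueError(f"means and sds must have length {k} (active strategies)")
    if np.any(sd < 0.0):
        raise ValueError("sds must be >= 0")
    if corr.shape != (k, k) or not np.allclose(corr, corr.T):
        raise ValueError(f"correlation must be a symmetric {k}x{k} matrix")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    z = rng.standard_normal((n_draws, k))
    log_or = mean + (z @ chol.T) * sd
    pi = expit(baseline_logodds + log_or)
    draws = np.concatenate([np.zeros((n_draws, 1)), pi], axis=1)
    return EffectivenessPosterior(draws, note="synthetic posterior emulation")


def write_posterior(posterior: EffectivenessPosterior, path) -> None:
    """Write draws to CSV (strategy-labelled columns, >=12 significant digits)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(posterior.labels)
        for row in posterior.draws:
            writer.writerow([f"{x:.17g}" for x in row])


def read_posterior(path) -> EffectivenessPosterior:
    """Read a posterior CSV written by :func:`write_posterior`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: no draws")
        labels = tuple(h.strip() for h in header)
        if labels != STRATEGY_LABELS:
            raise ValueError(
                f"{path}: expected {len(STRATEGY_LABELS)} strategy columns "
                f"{STRATEGY_LABELS}, got {labels}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(STRATEGY_LABELS):
                raise ValueError(f"{path}:{lineno}: ragged row with {len(row)} fields")
            rows.append([float(x) for x in row])
    if not rows:
        raise ValueError(f"{path}: no draws")
    return EffectivenessPosterior(np.asarray(rows))
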