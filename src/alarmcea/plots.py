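"""Plotting helpers: acceptability curves and the cost-effectiveness plane."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt

from .cea import FRONTIER, CEACResult, FrontierResult

__all__ = ["plot_ceac", "plot_frontier"]


def plot_ceac(result: CEACResult, ax=None):
    """Cost-effectiveness acceptability curves, one line per strategy."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for j, label in enumerate(result.labels):
        ax.plot(result.thresholds, result.probabilities[:, j], label=label)
    ax.set_xlabel("Willingness to pay (GBP per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return ax


def plot_frontier(result: FrontierResult, ax=None):
    """Per-strategy mean outcomes on the cost-effectiveness plane with the frontier."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    on = [i for i, s in enumerate(result.status) if s == FRONTIER]
    off = [i for i in range(len(result.labels)) if i not in on]
    ax.plot(result.qalys[list(on)], result.costs[list(on)], "o-", label="frontier")
    if off:
        ax.plot(result.qalys[off], result.costs[off], "x", label="excluded")
    for i, label in enumerate(result.labels):
        ax.annotate(label, (result.qalys[i], result.costs[i]), fontsize=8,
                    textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("Expected QALYs")
    ax.set_ylabel("Expected cost (GBP)")
    ax.legend(fontsize=8)
    return ax
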