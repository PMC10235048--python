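"""Publication-style figures for curves, distributions, and coefficients.

Every function draws on a provided matplotlib Axes (or creates one) and
returns it, so figures compose. Colors follow the task convention:
blue Observe, red Estimate, yellow Intervene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BLOCK_COLORS = {"Observe1": "#1f77b4", "Observe2": "#1f77b4",
                "Estimate": "#d62728", "Intervene": "#e6b412"}


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_psychometric_curve(curve: pd.DataFrame, ax=None, color=None,
                            label: str | None = None):
    """Empirical reveal fractions per dEV with binomial error bars and,
    when present, the fitted curve overlay."""
    ax = _ax(ax)
    ax.errorbar(curve["delta_ev"], 100 * curve["frac_reveal_hivar"],
                yerr=100 * curve["se"], fmt="o", ms=4, color=color, label=label)
    if "fitted" in curve:
        ax.plot(curve["delta_ev"], 100 * curve["fitted"], "-", color=color)
    ax.axhline(50, ls=":", lw=0.8, color="gray")
    ax.set_xlabel("ΔEV (points)")
    ax.set_ylabel("% reveal hiVar")
    ax.set_ylim(-2, 102)
    return ax


def plot_efficiency_distributions(efficiency: pd.DataFrame, ax=None,
                                  blocks=("Observe1", "Estimate", "Intervene")):
    """Per-block distributions of %reveal hiVar across participants."""
    ax = _ax(ax)
    bins = np.linspace(0, 100, 26)
    for block in blocks:
        vals = efficiency.loc[efficiency["block"] == block, "pct_reveal_hivar"]
        ax.hist(vals, bins=bins, histtype="step", lw=1.5,
                color=BLOCK_COLORS.get(block), label=block, density=True)
    ax.set_xlabel("% reveal hiVar")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    return ax


def plot_coefficient_forest(coefficients: pd.DataFrame, ax=None):
    """Forest plot of decoder coefficients (mean and 95% CI per trait),
    ordered by absolute effect size; significant traits drawn solid."""
    ax = _ax(ax)
    tab = coefficients.copy()
    tab["absmean"] = tab["mean"].abs()
    tab = tab.sort_values("absmean")
    y = np.arange(len(tab))
    for i, (_, row) in enumerate(tab.iterrows()):
        color = "black" if row["significant"] else "lightgray"
        ax.plot([row["ci_lo"], row["ci_hi"]], [i, i], "-", color=color, lw=1.5)
        ax.plot(row["mean"], i, "o", color=color, ms=4)
    ax.axvline(0, ls=":", lw=0.8, color="gray")
    ax.set_yticks(y)
    ax.set_yticklabels(tab["predictor"])
    ax.set_xlabel("coefficient (β)")
    return ax


def plot_strategy_groups(consistency: dict, ax=None):
    """Bar chart of the eight cross-block Uncertainty-only patterns."""
    ax = _ax(ax)
    counts = consistency["group_counts"]
    keys = sorted(counts)
    ax.bar(range(len(keys)), [counts[k] for k in keys], color="#555555")
    ax.set_xticks(range(len(keys)))
    ax.set_xticklabels(keys, rotation=45)
    ax.set_xlabel("Uncertainty-only pattern (Observe1, 1st, 2nd instrumental)")
    ax.set_ylabel("participants")
    for i, k in enumerate(keys):
        ax.text(i, counts[k], str(counts[k]), ha="center", va="bottom", fontsize=8)
    return ax
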