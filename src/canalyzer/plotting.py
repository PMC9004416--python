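"""Figure export: two-curve panel, H-L panel, ranked delta bars."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_curves", "plot_hl", "plot_ranked_deltas"]

_COLORS = {0: "#2166ac", 1: "#b2182b"}   # low blue, high red


def plot_curves(curve_high: pd.DataFrame, curve_low: pd.DataFrame,
                ylabel: str = "prevalence", ax=None):
    """Dot plot of the two prevalence/trait-mean curves by PGS percentile."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for curve, label in ((curve_low, "low exposure"),
                         (curve_high, "high exposure")):
        env = int(curve["env"].iloc[0])
        ax.plot(curve["bin_index"], curve["value"], ".",
                color=_COLORS[env], label=label, markersize=4)
    ax.set_xlabel("PGS percentile")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    return ax


def plot_hl(hl: pd.DataFrame, perm_band: np.ndarray | None = None, ax=None):
    """H-L difference per percentile, optionally with a permutation band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if perm_band is not None and len(perm_band):
        lim = float(np.max(np.abs(perm_band)))
        ax.axhspan(-lim, lim, color="0.85", zorder=0,
                   label="permutation range")
    ax.axhline(0.0, color="0.4", lw=0.8)
    ax.plot(hl["bin_index"], hl["diff"], ".", color="0.15", markersize=4)
    ax.set_xlabel("PGS percentile")
    ax.set_ylabel("high − low")
    return ax


def plot_ranked_deltas(results: pd.DataFrame, delta_col: str = "delta_int",
                       ax=None):
    """Ranked bar chart of per-exposure deltas colored by label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    table = results.sort_values(delta_col, ascending=False)
    palette = {"decanalization": "#b2182b", "canalization": "#2166ac",
               "suggestive_decanalization": "#ef8a62",
               "suggestive_canalization": "#67a9cf"}
    colors = [palette.get(lbl, "0.6") for lbl in table.get("label", [])]
    ax.bar(range(len(table)), table[delta_col], color=colors)
    ax.set_xticks(range(len(table)))
    ax.set_xticklabels(table["exposure"], rotation=90, fontsize=7)
    ax.set_ylabel(delta_col)
    ax.axhline(0.0, color="0.4", lw=0.8)
    return ax
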