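"""Percentile prevalence-risk curves and tail statistics.

The empirical object every downstream stage consumes is the per-percentile
curve: individuals are binned by PGS percentile on the pooled cohort (both
exposure strata together, so the two curves share one x-axis), and within
each bin and stratum the case fraction (binary trait) or trait mean
(continuous trait) is recorded together with the bin's mean PGS and count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TailDelta",
    "percentile_bins",
    "build_curve",
    "hl_curve",
    "tail_delta",
    "env_ratio_curve",
]


@dataclass
class TailDelta:
    """Right-minus-left tail deviation in the H-L difference.

    ``left_dev`` / ``right_dev`` are the high-minus-low differences in mean
    outcome among individuals whose PGS lies beyond ``sd_mult`` standard
    deviations below / above the pooled PGS mean; ``delta = right - left``.
    A pure additive environment shift moves both tails equally and cancels
    in delta; an interaction widens one tail more than the other.
    """

    left_dev: float
    right_dev: float
    delta: float
    sd_mult: float = 2.0


def percentile_bins(pgs, n_bins: int = 100) -> np.ndarray:
    """Assign each individual to a rank-based percentile bin (0-based).

    Bins are computed on the pooled cohort with near-equal counts; ties get
    their average rank and are then split stably, so the assignment is
    deterministic and independent of row order up to tie groups.
    """
    pgs = np.asarray(pgs, dtype=float)
    n = len(pgs)
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} individuals, got {n}")
    # stable argsort: ties keep input order, then average-rank groups land in
    # contiguous bins exactly as a rank-then-split oracle would produce
    order = np.argsort(pgs, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def build_curve(cohort: pd.DataFrame, env: int, bins: np.ndarray,
                n_bins: int = 100) -> pd.DataFrame:
    """Per-bin mean PGS, outcome value and count for one exposure stratum.

    Returns a DataFrame with columns ``bin_index`` (1-based), ``mean_pgs``,
    ``value``, ``count`` and ``env``; bins with no stratum members get
    NaN value and count 0 (downstream stages drop them).
    """
    mask = cohort["env"].to_numpy() == env
    if not mask.any():
        raise ValueError(f"stratum env={env} is empty")
    b = np.asarray(bins)[mask]
    pgs = cohort["pgs"].to_numpy()[mask]
    y = cohort["trait"].to_numpy()[mask]

    count = np.bincount(b, minlength=n_bins).astype(float)
    sum_y = np.bincount(b, weights=y, minlength=n_bins)
    sum_p = np.bincount(b, weights=pgs, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(count > 0, sum_y / np.maximum(count, 1), np.nan)
        mean_pgs = np.where(count > 0, sum_p / np.maximum(count, 1), np.nan)
    return pd.DataFrame({
        "bin_index": np.arange(1, n_bins + 1),
        "mean_pgs": mean_pgs,
        "value": value,
        "count": count.astype(int),
        "env": env,
    })


def hl_curve(high: pd.DataFrame, low: pd.DataFrame) -> pd.DataFrame:
    """High-minus-low difference per bin; bins empty in either stratum drop."""
    if len(high) != len(low) or not np.array_equal(
            high["bin_index"].to_numpy(), low["bin_index"].to_numpy()):
        raise ValueError("curves were built with mismatched binning")
    ok = high["value"].notna().to_numpy() & low["value"].notna().to_numpy()
    return pd.DataFrame({
        "bin_index": high["bin_index"].to_numpy()[ok],
        "diff": (high["value"].to_numpy() - low["value"].to_numpy())[ok],
    })


def _tail_masks(pgs: np.ndarray, sd_mult: float):
    mean, sd = pgs.mean(), pgs.std()
    return pgs < mean - sd_mult * sd, pgs > mean + sd_mult * sd


def tail_delta(cohort: pd.DataFrame, sd_mult: float = 2.0) -> TailDelta:
    """Observed tail delta from individual-level PGS cutoffs.

    Tail membership uses mean +/- sd_mult * SD of the pooled PGS (for a
    normal PGS and sd_mult=2, roughly the outer 2.3% on each side), not the
    outermost percentile bins.
    """
    pgs = cohort["pgs"].to_numpy(dtype=float)
    y = cohort["trait"].to_numpy(dtype=float)
    env = cohort["env"].to_numpy()
    left, right = _tail_masks(pgs, sd_mult)

    devs = []
    for side, mask in (("left", left), ("right", right)):
        for e in (0, 1):
            if not (mask & (env == e)).any():
                raise ValueError(
                    f"{side} tail beyond {sd_mult} SD has no individuals "
                    f"in stratum env={e}")
        devs.append(y[mask & (env == 1)].mean() - y[mask & (env == 0)].mean())
    left_dev, right_dev = devs
    return TailDelta(left_dev=left_dev, right_dev=right_dev,
                     delta=right_dev - left_dev, sd_mult=sd_mult)


def env_ratio_curve(cohort: pd.DataFrame, bins: np.ndarray,
                    n_bins: int = 100) -> tuple[pd.DataFrame, float]:
    """Per-bin ratio of high- to low-exposure counts, and its trend.

    Under gene-environment independence the ratio is flat; a PGS-exposure
    correlation tilts it.  Returns the per-bin table (ratio NaN where the
    low count is zero) and the Pearson correlation of ratio with bin index
    over defined bins.
    """
    env = cohort["env"].to_numpy()
    b = np.asarray(bins)
    hi = np.bincount(b[env == 1], minlength=n_bins).astype(float)
    lo = np.bincount(b[env == 0], minlength=n_bins).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / np.maximum(lo, 1), np.nan)
    table = pd.DataFrame({
        "bin_index": np.arange(1, n_bins + 1),
        "n_high": hi.astype(int),
        "n_low": lo.astype(int),
        "ratio": ratio,
    })
    ok = np.isfinite(ratio)
    corr = float(stats.pearsonr(table["bin_index"].to_numpy()[ok],
                                ratio[ok]).statistic) if ok.sum() > 2 else np.nan
    return table, corr
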