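"""Permutation screen for PGS-by-environment interaction.

The provisional screen asks two things of the high-minus-low (H-L)
difference curve across PGS percentiles: (1) its smoothed derivative is
consistently one-signed and its median exceeds, in absolute value, the
medians obtained from cohorts with randomly permuted exposure labels; and
(2) the absolute linear slope of the H-L curve exceeds all permuted slopes.
Exceedance over all of ``n_perm`` permutations corresponds to an empirical
one-sided p below 1/(n_perm+1) per condition; requiring both is more
conservative.

Trait-exposure pairs that fail the interaction screen are still classified:
a constant upward displacement of one curve (mean H-L exceeding all permuted
mean offsets) is an additive shift, and a significant slope whose smoothed
derivative changes sign across the middle of the risk range is flagged
nonmonotonic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import build_curve, hl_curve, percentile_bins

__all__ = [
    "ScreenResult",
    "smoothed_derivative",
    "permutation_null",
    "screen_pgsxe",
    "classify_shift",
    "orient_high_low",
]


@dataclass
class ScreenResult:
    slope_obs: float
    median_derivative: float
    mean_offset: float
    perm_slopes: np.ndarray
    perm_median_derivs: np.ndarray
    perm_mean_offsets: np.ndarray
    monotonic: bool
    passes: bool
    shift_class: str = "none"   # none | additive_shift | interaction | nonmonotonic
    high_env: int = 1           # stratum relabeled as "high" (elevated risk)
    n_bins: int = 100
    window: int = 11

    def to_record(self) -> dict:
        return {
            "slope_obs": self.slope_obs,
            "median_derivative": self.median_derivative,
            "mean_offset": self.mean_offset,
            "monotonic": self.monotonic,
            "passes": self.passes,
            "shift_class": self.shift_class,
            "high_env": self.high_env,
            "perm_slope_max_abs": float(np.max(np.abs(self.perm_slopes))),
            "perm_median_deriv_max_abs":
                float(np.max(np.abs(self.perm_median_derivs))),
        }


def orient_high_low(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Relabel strata so env=1 is the one with elevated overall risk/mean.

    Returns the (possibly relabeled) cohort and the original label of the
    stratum now called high.  The elevated-risk convention makes slopes and
    deltas comparable across exposures; it can flip the intuitive reading
    of an exposure (a known caveat of the convention).
    """
    means = cohort.groupby("env")["trait"].mean()
    if len(means) != 2:
        raise ValueError("cohort must contain exactly two exposure strata")
    high_env = int(means.idxmax())
    if high_env == 0:
        cohort = cohort.assign(env=1 - cohort["env"].to_numpy())
    return cohort, high_env


def smoothed_derivative(hl: pd.DataFrame, window: int = 11) -> np.ndarray:
    """First differences of the moving-average-smoothed H-L curve.

    A centered moving average of odd ``window`` is applied to the per-bin
    differences before differencing; raw per-percentile differences are too
    noisy for any consistency-of-sign statement.  Output length is
    ``n_bins - window``.
    """
    diff = np.asarray(hl["diff"], dtype=float)
    n = len(diff)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window >= n:
        raise ValueError(f"window={window} must be smaller than the number of "
                         f"bins ({n})")
    if window == 1:
        smooth = diff
    else:
        kernel = np.full(window, 1.0 / window)
        smooth = np.convolve(diff, kernel, mode="valid")
    return np.diff(smooth)


def _linear_slope(hl: pd.DataFrame) -> float:
    x = np.asarray(hl["bin_index"], dtype=float)
    y = np.asarray(hl["diff"], dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    return float(x @ (y - y.mean()) / denom) if denom > 0 else 0.0


def _hl_stats(cohort: pd.DataFrame, bins: np.ndarray, n_bins: int,
              window: int) -> tuple[float, float, float, np.ndarray]:
    high = build_curve(cohort, 1, bins, n_bins)
    low = build_curve(cohort, 0, bins, n_bins)
    hl = hl_curve(high, low)
    deriv = smoothed_derivative(hl, window)
    return (_linear_slope(hl), float(np.median(deriv)),
            float(hl["diff"].mean()), deriv)


def permutation_null(cohort: pd.DataFrame, bins: np.ndarray | None = None,
                     n_perm: int = 100, n_bins: int = 100, window: int = 11,
                     seed=0) -> pd.DataFrame:
    """Null distribution of H-L statistics under exposure-label permutation.

    Each permutation reshuffles the environment labels while keeping the
    stratum sizes fixed, rebuilds both curves on the same pooled percentile
    bins, and records the linear slope, the median smoothed derivative and
    the mean offset of the resulting H-L curve.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if bins is None:
        bins = percentile_bins(cohort["pgs"].to_numpy(), n_bins)
    rng = np.random.default_rng(seed)
    env = cohort["env"].to_numpy()
    work = cohort.copy()
    rows = []
    for _ in range(n_perm):
        work["env"] = rng.permutation(env)
        slope, med, off, _ = _hl_stats(work, bins, n_bins, window)
        rows.append((slope, med, off))
    return pd.DataFrame(rows, columns=["slope", "median_deriv", "mean_offset"])


def screen_pgsxe(cohort: pd.DataFrame, n_perm: int = 100, n_bins: int = 100,
                 window: int = 11, seed=0,
                 monotone_frac: float = 0.8) -> ScreenResult:
    """Run the two-condition permutation screen on one trait-exposure pair.

    ``monotone_frac`` is the fraction of smoothed-derivative values that
    must share the sign of their median for the curve to count as
    consistently monotonic.
    """
    cohort, high_env = orient_high_low(cohort)
    bins = percentile_bins(cohort["pgs"].to_numpy(), n_bins)
    slope, med, offset, deriv = _hl_stats(cohort, bins, n_bins, window)
    perms = permutation_null(cohort, bins=bins, n_perm=n_perm, n_bins=n_bins,
                             window=window, seed=seed)

    sign = np.sign(med)
    monotonic = bool(sign != 0 and
                     np.mean(np.sign(deriv) == sign) >= monotone_frac)
    deriv_exceeds = bool(abs(med) > np.abs(perms["median_deriv"]).max())
    slope_exceeds = bool(abs(slope) > np.abs(perms["slope"]).max())
    passes = monotonic and deriv_exceeds and slope_exceeds

    result = ScreenResult(
        slope_obs=slope, median_derivative=med, mean_offset=offset,
        perm_slopes=perms["slope"].to_numpy(),
        perm_median_derivs=perms["median_deriv"].to_numpy(),
        perm_mean_offsets=perms["mean_offset"].to_numpy(),
        monotonic=monotonic, passes=passes, high_env=high_env,
        n_bins=n_bins, window=window)
    result.shift_class = classify_shift(result, deriv, slope_exceeds)
    return result


def classify_shift(screen: ScreenResult, deriv: np.ndarray,
                   slope_exceeds: bool) -> str:
    """Four-way classification of the H-L curve shape.

    interaction: both screen conditions met.  nonmonotonic: the smoothed
    derivative flips sign in a sustained way between the lower and upper
    halves of the risk range, with both half-medians outside the permuted
    median-derivative band (a symmetric hump has near-zero linear slope, so
    the half-range derivatives carry the signal).  additive_shift: neither
    of the above, but the mean H-L offset exceeds all permuted mean offsets
    (curve displaced, not tilted).  none otherwise.
    """
    if screen.passes:
        return "interaction"
    half = len(deriv) // 2
    lower, upper = np.median(deriv[:half]), np.median(deriv[half:])
    perm_band = np.abs(screen.perm_median_derivs).max()
    if lower * upper < 0 and min(abs(lower), abs(upper)) > perm_band:
        return "nonmonotonic"
    offset_exceeds = (abs(screen.mean_offset)
                      > np.abs(screen.perm_mean_offsets).max())
    if offset_exceeds:
        return "additive_shift"
    return "none"
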