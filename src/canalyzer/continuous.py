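"""Canalization analysis for continuous traits.

The continuous pipeline works on the rank-based inverse-normal-transformed
(INT) trait after covariate adjustment, which removes scale and skew and
makes the high/low comparison conservative.  The exponential risk model is
fitted freely in the low-exposure stratum; the high stratum is then fitted
with its modifiable baseline constrained to the low stratum's estimate, so
that the two curves agree at the median of genetic risk and only the
setpoint and calibration factor shape the difference.  The model-implied
tail delta is compared against the same statistic recomputed under
exposure-label permutations (the whole pipeline, including both fits, is
re-run per permutation); the model-implied trait variance per stratum gives
a concordant second criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .riskmodel import ExponentialRisk, FitResult, expected_tail_delta
from .simulate import COVARIATE_NAMES

__all__ = [
    "InteractionRegressionFit",
    "ContinuousDeltaResult",
    "adjust_covariates",
    "inverse_normal_transform",
    "interaction_regression",
    "continuous_canalization",
    "matched_prevalence_threshold",
]


def adjust_covariates(cohort: pd.DataFrame,
                      covariate_names=COVARIATE_NAMES) -> np.ndarray:
    """Residualize the trait on covariates, preserving the grand mean."""
    y = cohort["trait"].to_numpy(dtype=float)
    X = cohort[list(covariate_names)].to_numpy(dtype=float)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(cohort[list(covariate_names)].to_numpy(
            dtype=float).T)
        bad = [covariate_names[i] for i in range(len(covariate_names))
               for j in range(i)
               if abs(corr[i, j]) > 1 - 1e-10]
        raise ValueError(f"collinear covariates: {bad or covariate_names}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta + y.mean()


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Blom rank-based inverse normal transform.

    z_i = Phi^{-1}((r_i - offset) / (n - 2*offset + 1)) with average ranks
    for ties; the default offset 3/8 is Blom's.  Invariant under any
    strictly monotone transform of the input.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(values) == 0:
        raise ValueError("constant input has no meaningful ranks")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))


@dataclass
class InteractionRegressionFit:
    """OLS fit of trait ~ PGS + Env + PGS:Env + covariates."""

    alpha: float
    beta: float
    gamma: float
    covariate_coeffs: dict
    epsilon_sd: float
    bse: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    scale: str = "raw"

    def summary(self) -> str:
        lines = [f"PGSxE interaction regression ({self.scale} scale)",
                 "-" * 54]
        for name, val in (("alpha (PGS)", self.alpha),
                          ("beta (Env)", self.beta),
                          ("gamma (PGSxEnv)", self.gamma)):
            key = name.split()[0]
            lines.append(f"{name:<16s} = {val:10.5f}   "
                         f"SE={self.bse.get(key, np.nan):.4g}   "
                         f"p={self.pvalues.get(key, np.nan):.3g}")
        lines.append(f"residual SD = {self.epsilon_sd:.5f}")
        return "\n".join(lines)


def _single_interaction_fit(y, pgs, env, covs, scale):
    X = np.column_stack([pgs, env, pgs * env, covs])
    names = ["alpha", "beta", "gamma"] + [f"cov{i}" for i in
                                          range(covs.shape[1])]
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (is the environment "
                         "constant?)")
    res = sm.OLS(y, X).fit()
    params = dict(zip(["const"] + names, res.params))
    bse = dict(zip(["const"] + names, res.bse))
    pvals = dict(zip(["const"] + names, res.pvalues))
    return InteractionRegressionFit(
        alpha=params["alpha"], beta=params["beta"], gamma=params["gamma"],
        covariate_coeffs={k: v for k, v in params.items()
                          if k.startswith("cov")},
        epsilon_sd=float(np.sqrt(res.scale)),
        bse={k: bse[k] for k in ("alpha", "beta", "gamma")},
        pvalues={k: pvals[k] for k in ("alpha", "beta", "gamma")},
        scale=scale)


def interaction_regression(cohort: pd.DataFrame,
                           covariate_names=COVARIATE_NAMES) -> dict:
    """Fit trait = alpha*PGS + beta*Env + gamma*(PGS*Env) + c*Cov + eps.

    Returns ``{"raw": fit, "int": fit}`` — the same regression on the raw
    trait and on its inverse-normal transform (the conservative scale).
    """
    env = cohort["env"].to_numpy(dtype=float)
    if len(np.unique(env)) < 2:
        raise ValueError("both exposure strata must be populated")
    pgs = cohort["pgs"].to_numpy(dtype=float)
    covs = cohort[list(covariate_names)].to_numpy(dtype=float)
    y_raw = cohort["trait"].to_numpy(dtype=float)
    return {
        "raw": _single_interaction_fit(y_raw, pgs, env, covs, "raw"),
        "int": _single_interaction_fit(inverse_normal_transform(y_raw),
                                       pgs, env, covs, "int"),
    }


@dataclass
class ContinuousDeltaResult:
    """Constrained-MBL tail delta versus its permutation distribution."""

    delta_obs_int: float
    perm_deltas: np.ndarray
    var_high: float
    var_low: float
    label: str
    fit_low: FitResult | None = None
    fit_high: FitResult | None = None
    delta_obs_raw: float = np.nan
    high_env: int = 1
    classifiable: bool = True

    def summary(self) -> str:
        lo, hi = (np.min(self.perm_deltas), np.max(self.perm_deltas)) \
            if len(self.perm_deltas) else (np.nan, np.nan)
        return (f"delta (INT scale) = {self.delta_obs_int:+.4f}  "
                f"permutation range [{lo:+.4f}, {hi:+.4f}]\n"
                f"model Var{{Y}}: high={self.var_high:.4f} "
                f"low={self.var_low:.4f}\nlabel = {self.label}")


def _constrained_delta(y, pgs, env, sd_mult):
    """Fit low freely, high with MBL tied to low; return delta + fits."""
    mask_low = env == 0
    fit_low = ExponentialRisk(y[mask_low], pgs[mask_low]).fit()
    fit_high = ExponentialRisk(y[~mask_low], pgs[~mask_low]).fit(
        fixed={"mbl": fit_low.model.mbl})
    delta = expected_tail_delta(fit_low.model, fit_high.model, sd_mult)
    return delta, fit_low, fit_high


def continuous_canalization(cohort: pd.DataFrame, n_perm: int = 100,
                            sd_mult: float = 2.0, seed=0,
                            covariate_names=COVARIATE_NAMES,
                            int_offset: float = 0.375
                            ) -> ContinuousDeltaResult:
    """Classify one continuous trait-exposure pair.

    Pipeline: adjust covariates -> inverse normal transform -> orient so
    env=1 is the higher-mean stratum -> exponential fit (low free, high
    with constrained MBL) -> model-implied tail delta -> compare with
    ``n_perm`` exposure-label permutations of the full pipeline.  Label is
    decanalization if delta exceeds every permuted delta, canalization if
    it is below every one, none otherwise.
    """
    from .curves import tail_delta as _obs_tail_delta
    from .screen import orient_high_low

    cohort, high_env = orient_high_low(cohort)
    adj = adjust_covariates(cohort, covariate_names)
    y = inverse_normal_transform(adj, offset=int_offset)
    pgs = cohort["pgs"].to_numpy(dtype=float)
    pgs = pgs - np.median(pgs)
    env = cohort["env"].to_numpy()

    try:
        delta_obs, fit_low, fit_high = _constrained_delta(y, pgs, env, sd_mult)
    except (ValueError, RuntimeError):
        return ContinuousDeltaResult(
            delta_obs_int=np.nan, perm_deltas=np.array([]),
            var_high=np.nan, var_low=np.nan, label="unclassifiable",
            high_env=high_env, classifiable=False,
            delta_obs_raw=np.nan)
    if not (fit_low.converged and fit_high.converged):
        return ContinuousDeltaResult(
            delta_obs_int=delta_obs, perm_deltas=np.array([]),
            var_high=np.nan, var_low=np.nan, label="unclassifiable",
            fit_low=fit_low, fit_high=fit_high, high_env=high_env,
            classifiable=False)

    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_perm)
    for i in range(n_perm):
        perm_env = rng.permutation(env)
        perm_deltas[i] = _constrained_delta(y, pgs, perm_env, sd_mult)[0]

    if delta_obs > perm_deltas.max():
        label = "decanalization"
    elif delta_obs < perm_deltas.min():
        label = "canalization"
    else:
        label = "none"

    # raw-scale observed tail delta (reported alongside, not classified)
    raw = cohort.assign(trait=adj)
    try:
        delta_raw = _obs_tail_delta(raw, sd_mult).delta
    except ValueError:
        delta_raw = np.nan

    return ContinuousDeltaResult(
        delta_obs_int=float(delta_obs), perm_deltas=perm_deltas,
        var_high=fit_high.model.moments()["variance"],
        var_low=fit_low.model.moments()["variance"],
        label=label, fit_low=fit_low, fit_high=fit_high,
        delta_obs_raw=float(delta_raw), high_env=high_env)


def matched_prevalence_threshold(cohort: pd.DataFrame, threshold: float,
                                 target_prevalence_from: int = 0
                                 ) -> tuple[dict, pd.DataFrame]:
    """Dichotomize a continuous trait at matched prevalence per stratum.

    The reference stratum uses the given trait ``threshold`` (e.g. BMI>30);
    the other stratum's cutoff is chosen so both strata have the same case
    fraction.  Returns ``(cutoffs, dichotomized cohort)`` where the cohort's
    trait column is replaced by the matched-prevalence case indicator,
    suitable for the binary pipeline.
    """
    env = cohort["env"].to_numpy()
    y = cohort["trait"].to_numpy(dtype=float)
    ref = target_prevalence_from
    other = 1 - ref
    y_ref = y[env == ref]
    y_other = y[env == other]
    if len(y_ref) == 0 or len(y_other) == 0:
        raise ValueError("both strata must be populated")
    prev = float((y_ref > threshold).mean())
    if not (0.0 < prev < 1.0):
        raise ValueError(
            f"threshold {threshold} yields degenerate prevalence {prev} in "
            f"the reference stratum")
    cutoff_other = float(np.quantile(y_other, 1.0 - prev))
    cutoffs = {ref: float(threshold), other: cutoff_other}
    cases = np.where(env == ref, y > cutoffs[ref], y > cutoffs[other])
    out = cohort.assign(trait=cases.astype(float))
    return cutoffs, out
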