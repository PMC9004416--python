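"""Expected tail deviations for binary traits under the liability threshold model.

Disease status is treated as a thresholded latent liability: within each PGS
percentile bin and environment stratum the liability is N(mu_i, 1), the case
threshold t = Phi^{-1}(1 - P_overall) is shared, and the bin's prevalence
determines its mean liability through

    mu_i = t - Phi^{-1}(1 - P_i).

Regressing mu_i on the bin's mean PGS and the environment indicator over the
(up to) 200 bin-by-environment points yields a null (no-interaction) model
whose implied prevalences give the deviation between the exposure curves
*expected* from the overall environment effect alone.  Canalization and
decanalization are declared when the observed tail delta departs from the
expected delta by more than a threshold number of SD units of the expected
delta's sampling distribution.

The module also houses the stratified per-variant odds-ratio comparison:
under the liability model, effect sizes estimated in a higher-prevalence
stratum are systematically attenuated even when the true liability effects
are identical, a phenomenon that mimics canalization if uncorrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .curves import TailDelta, build_curve, percentile_bins, tail_delta
from .simulate import GenotypePanel

logger = logging.getLogger("canalyzer")

__all__ = [
    "LiabilityBins",
    "LiabilityFit",
    "DeltaResult",
    "liability_threshold",
    "bin_liabilities",
    "LiabilityModel",
    "fit_liability_model",
    "expected_prevalence",
    "delta_expected",
    "departure_score",
    "analyze_binary_pair",
    "stratified_effect_sizes",
]


def liability_threshold(p_overall: float) -> float:
    """Case threshold t = Phi^{-1}(1 - P_overall) on the N(0,1) liability."""
    if not (0.0 < p_overall < 1.0):
        raise ValueError(f"prevalence must lie in (0, 1), got {p_overall}")
    return float(stats.norm.ppf(1.0 - p_overall))


@dataclass
class LiabilityBins:
    """Per-bin liabilities for both strata, sharing one threshold.

    ``table`` columns: bin_index, env, mean_pgs, observed_prevalence, mu.
    Bins with prevalence exactly 0 or 1 have infinite mu and are excluded
    (``n_dropped`` records how many).
    """

    table: pd.DataFrame
    threshold: float
    p_overall: float
    n_dropped: int = 0
    curve_table: pd.DataFrame | None = None   # all populated bins, with counts


def bin_liabilities(curve_high: pd.DataFrame, curve_low: pd.DataFrame,
                    p_overall: float) -> LiabilityBins:
    """Convert observed per-bin prevalences to per-bin mean liabilities.

    Bins with prevalence exactly 0 or 1 (infinite liability) are excluded
    from the regression table but retained in ``curve_table``: a zero
    prevalence is still a valid observation when averaging prevalences over
    tail bins.
    """
    t = liability_threshold(p_overall)
    frames = []
    dropped = 0
    for curve in (curve_low, curve_high):
        sub = curve[curve["count"] > 0][
            ["bin_index", "env", "mean_pgs", "value", "count"]].copy()
        ok = (sub["value"] > 0.0) & (sub["value"] < 1.0)
        dropped += int((~ok).sum())
        reg = sub[ok].drop(columns="count").copy()
        reg["mu"] = t - stats.norm.ppf(1.0 - reg["value"].to_numpy())
        frames.append((reg.rename(columns={"value": "observed_prevalence"}),
                       sub))
    table = pd.concat([f[0] for f in frames], ignore_index=True)
    curve_table = pd.concat([f[1] for f in frames], ignore_index=True)
    if table.empty or table["env"].nunique() < 2:
        raise ValueError("all percentile bins degenerate; cannot build "
                         "liability bins for both strata")
    if dropped:
        logger.info("dropped %d degenerate (prevalence 0/1) bins from the "
                    "liability regression", dropped)
    return LiabilityBins(table=table, threshold=t, p_overall=p_overall,
                         n_dropped=dropped, curve_table=curve_table)


@dataclass
class LiabilityFit:
    """OLS fit of mu_i = a*PGS + b*Env (+ d*PGS*Env) + c."""

    a: float
    b: float
    c: float
    d: float | None
    residual_sd: float
    n_points: int
    bse: dict = field(default_factory=dict)

    @property
    def with_interaction(self) -> bool:
        return self.d is not None

    def predict_mu(self, mean_pgs, env) -> np.ndarray:
        mean_pgs = np.asarray(mean_pgs, dtype=float)
        env = np.asarray(env, dtype=float)
        mu = self.a * mean_pgs + self.b * env + self.c
        if self.d is not None:
            mu = mu + self.d * mean_pgs * env
        return mu

    def summary(self) -> str:
        lines = ["Liability-threshold bin regression "
                 "(mu = a*PGS + b*Env%s + c)" %
                 (" + d*PGS*Env" if self.with_interaction else ""),
                 "-" * 54]
        for name in ("a", "b", "c") + (("d",) if self.with_interaction else ()):
            se = self.bse.get(name, np.nan)
            lines.append(f"{name} = {getattr(self, name):10.5f}   SE={se:.4g}")
        lines.append(f"residual SD = {self.residual_sd:.5f}   "
                     f"n_points = {self.n_points}")
        return "\n".join(lines)


class LiabilityModel:
    """Linear model for per-bin liabilities; ``fit()`` returns LiabilityFit."""

    def __init__(self, bins: LiabilityBins):
        self.bins = bins

    def fit(self, with_interaction: bool = False) -> LiabilityFit:
        tbl = self.bins.table
        if tbl["env"].nunique() < 2 or len(tbl) < 4:
            raise ValueError("need >= 4 bin points spanning both strata")
        x = tbl["mean_pgs"].to_numpy()
        e = tbl["env"].to_numpy(dtype=float)
        cols = [x, e]
        names = ["a", "b"]
        if with_interaction:
            cols.append(x * e)
            names.append("d")
        X = np.column_stack(cols + [np.ones(len(tbl))])
        names.append("c")
        y = tbl["mu"].to_numpy()
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise ValueError("rank-deficient liability design matrix")
        fitted = X @ beta
        resid = y - fitted
        dof = len(y) - X.shape[1]
        s2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = np.linalg.inv(X.T @ X) * s2
        bse = {n: float(np.sqrt(cov[i, i])) for i, n in enumerate(names)}
        coef = dict(zip(names, beta))
        return LiabilityFit(
            a=float(coef["a"]), b=float(coef["b"]), c=float(coef["c"]),
            d=float(coef["d"]) if with_interaction else None,
            residual_sd=float(np.sqrt(np.mean(resid ** 2))),
            n_points=len(y), bse=bse)


def fit_liability_model(bins: LiabilityBins,
                        with_interaction: bool = False) -> LiabilityFit:
    """Functional wrapper around :class:`LiabilityModel`."""
    return LiabilityModel(bins).fit(with_interaction=with_interaction)


def expected_prevalence(fit: LiabilityFit, bins: LiabilityBins) -> pd.DataFrame:
    """Model-implied prevalence per bin/stratum: E{P_i} = 1 - Phi(t - mu_i)."""
    tbl = bins.table.copy()
    mu = fit.predict_mu(tbl["mean_pgs"], tbl["env"])
    tbl["expected_mu"] = mu
    tbl["expected_prevalence"] = stats.norm.sf(bins.threshold - mu)
    return tbl


def _curve_tail_delta(tbl: pd.DataFrame, prev_col: str, pgs_mean: float,
                      pgs_sd: float, sd_mult: float) -> float:
    """Tail delta of per-bin prevalences, tails at individual-level cutoffs.

    Bins whose mean PGS lies beyond mean +/- sd_mult*SD contribute, with
    count-weighted averaging so the statistic matches the individual-level
    observed delta convention.
    """
    devs = []
    for sign in (-1, 1):
        if sign < 0:
            sel = tbl[tbl["mean_pgs"] < pgs_mean - sd_mult * pgs_sd]
        else:
            sel = tbl[tbl["mean_pgs"] > pgs_mean + sd_mult * pgs_sd]
        means = {}
        for e, grp in sel.groupby("env"):
            w = grp["count"].to_numpy(dtype=float) if "count" in grp \
                else np.ones(len(grp))
            means[e] = float(np.average(grp[prev_col].to_numpy(), weights=w))
        if len(means) < 2:
            raise ValueError(
                "no percentile bin lies beyond the "
                f"{'left' if sign < 0 else 'right'} tail cutoff in both strata")
        devs.append(means[1] - means[0])
    return devs[1] - devs[0]


def delta_expected(fit: LiabilityFit, bins: LiabilityBins, pgs_mean: float,
                   pgs_sd: float, n_iter: int = 10, sd_mult: float = 2.0,
                   seed=0) -> tuple[float, float, np.ndarray]:
    """Sampled expectation of the tail delta under the null liability fit.

    Each iteration perturbs the fitted bin liabilities with N(0,
    residual_sd^2) noise, converts them to prevalences and recomputes the
    tail delta over all populated bins; the mean and SD over iterations
    quantify the delta expected from the overall environment effect alone
    plus its sampling noise.
    """
    if fit.with_interaction:
        raise ValueError("delta_expected is defined for the null "
                         "(no-interaction) fit")
    rng = np.random.default_rng(seed)
    tbl = (bins.curve_table if bins.curve_table is not None
           else bins.table.assign(count=1)).copy()
    mu_hat = fit.predict_mu(tbl["mean_pgs"], tbl["env"])
    deltas = np.empty(n_iter)
    for i in range(n_iter):
        mu = mu_hat + rng.normal(0.0, fit.residual_sd, size=len(mu_hat))
        tbl["sampled_prevalence"] = stats.norm.sf(bins.threshold - mu)
        deltas[i] = _curve_tail_delta(tbl, "sampled_prevalence", pgs_mean,
                                      pgs_sd, sd_mult)
    return float(deltas.mean()), float(deltas.std(ddof=0)), deltas


@dataclass
class DeltaResult:
    """Observed versus expected tail delta and the (de)canalization label."""

    delta_obs: float
    delta_exp_mean: float
    delta_exp_sd: float
    scale_sd: float
    departure: float
    label: str
    ci_flag: bool = False

    def summary(self) -> str:
        return (f"delta_obs={self.delta_obs:.4f}  "
                f"delta_exp={self.delta_exp_mean:.4f} "
                f"(SD {self.delta_exp_sd:.4f})  "
                f"departure={self.departure:+.3f} SD  label={self.label}"
                + ("  [outside 95% CI]" if self.ci_flag else ""))


def departure_score(delta_obs: float, delta_exp_mean: float, scale_sd: float,
                    delta_exp_sd: float = np.nan,
                    conservative: float = 2.0,
                    suggestive: float = 1.3,
                    ci_flag: bool = False) -> DeltaResult:
    """Score and label the observed-minus-expected tail deviation.

    ``scale_sd`` is the mean expected-delta SD across the exposure battery
    for the trait; positive departures indicate decanalization (greater
    divergence at the genetic extremes than the overall environment effect
    predicts), negative ones canalization.
    """
    if not (scale_sd > 0):
        raise ValueError(f"scale_sd must be > 0, got {scale_sd}")
    departure = (delta_obs - delta_exp_mean) / scale_sd
    if departure >= conservative:
        label = "decanalization"
    elif departure <= -conservative:
        label = "canalization"
    elif departure >= suggestive:
        label = "suggestive_decanalization"
    elif departure <= -suggestive:
        label = "suggestive_canalization"
    else:
        label = "none"
    return DeltaResult(delta_obs=delta_obs, delta_exp_mean=delta_exp_mean,
                       delta_exp_sd=float(delta_exp_sd), scale_sd=scale_sd,
                       departure=float(departure), label=label,
                       ci_flag=ci_flag)


def analyze_binary_pair(cohort: pd.DataFrame, n_bins: int = 100,
                        n_iter: int = 10, sd_mult: float = 2.0,
                        seed=0) -> dict:
    """Observed delta, expected delta and liability fits for one pair.

    Returns a dict with the observed :class:`TailDelta`, the null and
    interaction :class:`LiabilityFit` objects, the expected-delta mean/SD,
    and the 95%-CI exceedance flag.  Battery-level scaling and labeling
    happen in the pipeline, where the cross-exposure scale_sd is known.
    """
    from .screen import orient_high_low

    cohort, high_env = orient_high_low(cohort)
    pgs = cohort["pgs"].to_numpy()
    bins = percentile_bins(pgs, n_bins)
    curve_h = build_curve(cohort, 1, bins, n_bins)
    curve_l = build_curve(cohort, 0, bins, n_bins)
    p_overall = float(cohort["trait"].mean())
    lbins = bin_liabilities(curve_h, curve_l, p_overall)
    model = LiabilityModel(lbins)
    fit_null = model.fit(with_interaction=False)
    fit_int = model.fit(with_interaction=True)
    obs = tail_delta(cohort, sd_mult)
    exp_mean, exp_sd, draws = delta_expected(
        fit_null, lbins, pgs.mean(), pgs.std(), n_iter=n_iter,
        sd_mult=sd_mult, seed=seed)
    if exp_sd > 0:
        ci = (obs.delta < exp_mean - 1.96 * exp_sd
              or obs.delta > exp_mean + 1.96 * exp_sd)
    else:
        ci = obs.delta != exp_mean
    return {
        "high_env": high_env,
        "observed": obs,
        "fit_null": fit_null,
        "fit_interaction": fit_int,
        "liability_bins": lbins,
        "delta_exp_mean": exp_mean,
        "delta_exp_sd": exp_sd,
        "delta_exp_draws": draws,
        "ci_flag": bool(ci),
    }


def stratified_effect_sizes(panel: GenotypePanel, case_status, env,
                            method: str = "counts") -> pd.DataFrame:
    """Per-variant log odds ratios estimated separately in each stratum.

    ``method='counts'`` (default) uses the 2x2 effect-allele count table
    with a Haldane-Anscombe 0.5 correction applied to zero cells;
    ``method='logistic'`` fits a per-variant dosage logistic regression.
    Returns a DataFrame with columns variant_id, logor_low, logor_high and
    a ``corrected`` flag per stratum.
    """
    case_status = np.asarray(case_status).astype(int)
    env = np.asarray(env).astype(int)
    n = panel.n_individuals
    if len(case_status) != n or len(env) != n:
        raise ValueError("case_status and env must match the panel size")
    for e in (0, 1):
        sel = env == e
        if case_status[sel].min(initial=1) == 1 or \
           case_status[sel].max(initial=0) == 0:
            raise ValueError(f"stratum env={e} lacks cases or controls")

    out = {"variant_id": panel.variant_ids}
    for e, tag in ((0, "low"), (1, "high")):
        sel = env == e
        d = panel.dosages[sel]
        cc = case_status[sel]
        if method == "counts":
            n_case, n_ctrl = cc.sum(), (1 - cc).sum()
            alt_case = d[cc == 1].sum(axis=0)
            alt_ctrl = d[cc == 0].sum(axis=0)
            ref_case = 2.0 * n_case - alt_case
            ref_ctrl = 2.0 * n_ctrl - alt_ctrl
            cells = np.vstack([alt_case, ref_case, alt_ctrl, ref_ctrl])
            zero = (cells == 0).any(axis=0)
            cells = cells + 0.5 * zero  # Haldane-Anscombe on affected variants
            logor = (np.log(cells[0]) - np.log(cells[1])
                     - np.log(cells[2]) + np.log(cells[3]))
            out[f"logor_{tag}"] = logor
            out[f"corrected_{tag}"] = zero
        elif method == "logistic":
            import statsmodels.api as sm
            logor = np.empty(panel.n_variants)
            corrected = np.zeros(panel.n_variants, dtype=bool)
            for j in range(panel.n_variants):
                X = sm.add_constant(d[:, j])
                try:
                    res = sm.Logit(cc, X).fit(disp=0, maxiter=100)
                    logor[j] = res.params[1]
                    corrected[j] = not res.mle_retvals.get("converged", True)
                except Exception:
                    logor[j] = np.nan
                    corrected[j] = True
            out[f"logor_{tag}"] = logor
            out[f"corrected_{tag}"] = corrected
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(out)
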