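"""The exponential setpoint / modifiable-baseline / calibration-factor model.

Risk (or a continuous trait) is modelled as

    trait = SP + MBL * exp(PGS / CF)

where SP (setpoint) is the component of risk independent of genetics, MBL
(modifiable baseline) is the component amplified multiplicatively by the
polygenic score, and CF (calibration factor) divides the PGS so that larger
CF means weaker effective genetic modulation.  The PGS is centered to a
median of zero with observed standard deviation sigma, so the predicted
value at the median of genetic risk is SP + MBL.

Because exp(PGS/CF) of a normal PGS is lognormal, the model has closed-form
moments and truncated conditional expectations; these drive the expected
tail-deviation (delta) statistic used to classify canalization versus
decanalization of continuous traits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ExpRiskModel",
    "FitResult",
    "ExponentialRisk",
    "fit_exp_model",
    "expected_tail_delta",
]

_PARAM_NAMES = ("sp", "mbl", "cf")


@dataclass
class ExpRiskModel:
    """Parameter container: prediction, moments and tail expectations.

    Parameters
    ----------
    sp : setpoint, trait units.
    mbl : modifiable baseline, trait units, >= 0.
    cf : calibration factor, PGS score units, > 0.
    sigma : standard deviation of the (median-centered) PGS, score units.
    """

    sp: float
    mbl: float
    cf: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.cf <= 0:
            raise ValueError(f"cf must be > 0, got {self.cf}")
        if self.mbl < 0:
            raise ValueError(f"mbl must be >= 0, got {self.mbl}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def predict(self, pgs) -> np.ndarray | float:
        """sp + mbl * exp(pgs / cf); expects a median-centered PGS."""
        pgs = np.asarray(pgs, dtype=float)
        out = self.sp + self.mbl * np.exp(pgs / self.cf)
        return float(out) if out.ndim == 0 else out

    def moments(self) -> dict:
        """Closed-form median, mean and variance of the trait.

        With PGS ~ N(0, sigma^2), exp(PGS/cf) is lognormal, giving
        mean = sp + mbl * exp(sigma^2 / 2 cf^2) and
        variance = mbl^2 * (exp(2 sigma^2 / cf^2) - exp(sigma^2 / cf^2)).
        """
        r = (self.sigma / self.cf) ** 2
        return {
            "median": self.sp + self.mbl,
            "mean": self.sp + self.mbl * np.exp(r / 2.0),
            "variance": self.mbl ** 2 * (np.exp(2.0 * r) - np.exp(r)),
        }

    def tail_mean(self, side: str, sd_mult: float = 2.0) -> float:
        """Expected trait value conditional on a PGS tail.

        right: E{trait | PGS > sd_mult * sigma}
             = [sp*(1-Phi(k)) + mbl*(1-Phi(k - sigma/cf)) * e^(sigma^2/2cf^2)]
               / (1-Phi(k))
        left: the mirror image with lower-tail probabilities,
             = [sp*Phi(-k) + mbl*Phi(-k - sigma/cf) * e^(sigma^2/2cf^2)]
               / Phi(-k)

        both being exact truncated-lognormal conditional means.
        """
        k = float(sd_mult)
        r = self.sigma / self.cf
        growth = np.exp(r ** 2 / 2.0)
        if side == "right":
            p_tail = stats.norm.sf(k)
            p_shift = stats.norm.sf(k - r)
        elif side == "left":
            p_tail = stats.norm.cdf(-k)
            p_shift = stats.norm.cdf(-k - r)
        else:
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return float(self.sp + self.mbl * p_shift * growth / p_tail)

    def to_json(self, **extra) -> str:
        payload = {"sp": self.sp, "mbl": self.mbl, "cf": self.cf,
                   "sigma": self.sigma}
        payload.update(extra)
        return json.dumps(payload, indent=2)


def expected_tail_delta(model_low: ExpRiskModel, model_high: ExpRiskModel,
                        sd_mult: float = 2.0) -> float:
    """Model-implied delta between the two exposure strata.

    delta = [E{high|right} - E{low|right}] - [E{high|left} - E{low|left}].
    A pure setpoint shift cancels between the tails; a calibration-factor
    or modifiable-baseline difference does not.
    """
    right = (model_high.tail_mean("right", sd_mult)
             - model_low.tail_mean("right", sd_mult))
    left = (model_high.tail_mean("left", sd_mult)
            - model_low.tail_mean("left", sd_mult))
    return right - left


@dataclass
class FitResult:
    """Results of a nonlinear least-squares fit of the exponential model."""

    model: ExpRiskModel
    r_squared: float
    residual_sd: float
    converged: bool
    constrained: tuple = ()
    bse: dict = field(default_factory=dict)
    nobs: int = 0
    message: str = ""

    @property
    def params(self) -> dict:
        m = self.model
        return {"sp": m.sp, "mbl": m.mbl, "cf": m.cf}

    def to_json(self) -> str:
        return self.model.to_json(
            r_squared=self.r_squared, residual_sd=self.residual_sd,
            constrained=list(self.constrained))

    def summary(self) -> str:
        lines = ["Exponential risk model (trait = SP + MBL*exp(PGS/CF))",
                 "-" * 54]
        for name, value in self.params.items():
            se = self.bse.get(name)
            tag = " (fixed)" if name in self.constrained else (
                f"  SE={se:.4g}" if se is not None and np.isfinite(se) else "")
            lines.append(f"{name.upper():>4s} = {value:10.4f}{tag}")
        lines.append(f"sigma(PGS) = {self.model.sigma:.4f}")
        lines.append(f"R^2 = {self.r_squared:.4f}   residual SD = "
                     f"{self.residual_sd:.4f}   n = {self.nobs}")
        if not self.converged:
            lines.append(f"WARNING: fit did not converge ({self.message})")
        return "\n".join(lines)


class ExponentialRisk:
    """Nonlinear least-squares model for the exponential risk curve.

    Built from observed outcome values ``y`` and polygenic scores ``pgs``
    (optionally weighted, e.g. percentile-bin prevalences weighted by bin
    counts).  ``fit()`` returns a :class:`FitResult`.

    Parameters
    ----------
    y : array-like
        Outcome (trait value or per-bin prevalence).
    pgs : array-like
        Polygenic scores; centered to median zero unless ``center=False``.
    weights : array-like, optional
        Non-negative least-squares weights (counts).
    center : bool
        Center the PGS to median zero (the model's convention).
    """

    #: calibration-factor bounds relative to the PGS standard deviation
    CF_BOUND_FACTOR = 50.0

    def __init__(self, y, pgs, weights=None, center: bool = True,
                 sigma: float | None = None):
        y = np.asarray(y, dtype=float)
        pgs = np.asarray(pgs, dtype=float)
        if y.shape != pgs.shape:
            raise ValueError("y and pgs must have the same length")
        ok = np.isfinite(y) & np.isfinite(pgs)
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            ok &= np.isfinite(weights) & (weights > 0)
        y, pgs = y[ok], pgs[ok]
        if weights is not None:
            weights = weights[ok]
        if center:
            pgs = pgs - np.median(pgs)
        self.y = y
        self.pgs = pgs
        self.weights = weights
        if sigma is None:
            if weights is None:
                sigma = pgs.std()
            else:
                mu = np.average(pgs, weights=weights)
                sigma = np.sqrt(np.average((pgs - mu) ** 2, weights=weights))
        self.sigma = float(sigma)

    def _start(self, fixed: dict) -> dict:
        # sp0 = 5th percentile of outcome, mbl0 = median minus sp0 (floored),
        # cf0 = PGS SD: keeps exp argument near unity and parameters feasible
        sp0 = np.percentile(self.y, 5)
        mbl0 = max(np.median(self.y) - sp0, 1e-3)
        cf0 = max(self.sigma, 1e-6)
        start = {"sp": sp0, "mbl": mbl0, "cf": cf0}
        start.update(fixed)
        return start

    def fit(self, fixed: dict | None = None) -> FitResult:
        """Least-squares estimates of the free parameters.

        ``fixed`` maps parameter names (sp, mbl, cf) to values held
        constant; used e.g. for the constrained-MBL high/low comparison.
        """
        fixed = dict(fixed or {})
        unknown = set(fixed) - set(_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
        free = [p for p in _PARAM_NAMES if p not in fixed]
        n_distinct = len(np.unique(self.pgs))
        if n_distinct < max(len(free), 2):
            raise ValueError(
                f"need >= {max(len(free), 2)} distinct PGS values to fit "
                f"{len(free)} free parameters, got {n_distinct}")
        if len(self.y) < max(len(free), 1):
            raise ValueError("fewer observations than free parameters")
        start = self._start(fixed)

        sqw = np.sqrt(self.weights) if self.weights is not None else 1.0
        sd = max(self.sigma, 1e-12)
        lo = {"sp": -np.inf, "mbl": 0.0, "cf": sd / self.CF_BOUND_FACTOR}
        hi = {"sp": np.inf, "mbl": np.inf, "cf": sd * self.CF_BOUND_FACTOR}

        def unpack(theta):
            p = dict(fixed)
            p.update(dict(zip(free, theta)))
            return p

        def resid(theta):
            p = unpack(theta)
            return sqw * (self.y - (p["sp"] + p["mbl"]
                                    * np.exp(self.pgs / p["cf"])))

        def jac(theta):
            p = unpack(theta)
            e = np.exp(self.pgs / p["cf"])
            cols = {"sp": -np.ones_like(self.pgs),
                    "mbl": -e,
                    "cf": p["mbl"] * e * self.pgs / p["cf"] ** 2}
            return np.column_stack([sqw * cols[name] for name in free])

        if not free:
            raise ValueError("at least one parameter must be free")
        x0 = np.array([np.clip(start[p], lo[p], hi[p]) for p in free])
        sol = optimize.least_squares(
            resid, x0, jac=jac,
            bounds=([lo[p] for p in free], [hi[p] for p in free]),
            xtol=1e-12, ftol=1e-12, gtol=1e-10, method="trf")

        params = unpack(sol.x)
        at_bound = any(
            np.isclose(params["cf"], b, rtol=1e-6) for b in (lo["cf"], hi["cf"])
        ) if "cf" in free else False
        if at_bound:
            warnings.warn("calibration factor driven to its bound; the "
                          "exponential curvature is not identifiable on these "
                          "data", RuntimeWarning, stacklevel=2)

        r = sol.fun
        n, p_free = len(self.y), len(free)
        ss_res = float(r @ r)
        if self.weights is not None:
            ybar = np.average(self.y, weights=self.weights)
            ss_tot = float(np.sum(self.weights * (self.y - ybar) ** 2))
        else:
            ss_tot = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        dof = n - p_free
        resid_sd = np.sqrt(ss_res / dof) if dof > 0 else 0.0

        bse = {}
        if dof > 0:
            J = jac(sol.x)
            try:
                cov = np.linalg.inv(J.T @ J) * ss_res / dof
                for i, name in enumerate(free):
                    bse[name] = float(np.sqrt(max(cov[i, i], 0.0)))
            except np.linalg.LinAlgError:
                pass

        model = ExpRiskModel(sp=params["sp"], mbl=max(params["mbl"], 0.0),
                             cf=params["cf"], sigma=self.sigma)
        return FitResult(
            model=model,
            r_squared=float(np.clip(r2, 0.0, 1.0)) if np.isfinite(r2) else r2,
            residual_sd=float(resid_sd),
            converged=bool(sol.success) and not at_bound,
            constrained=tuple(sorted(fixed)),
            bse=bse, nobs=n, message=str(sol.message))


def fit_exp_model(pgs, y, weights=None, fixed=None, center: bool = True,
                  sigma: float | None = None) -> FitResult:
    """Functional wrapper around :class:`ExponentialRisk`."""
    return ExponentialRisk(y, pgs, weights=weights, center=center,
                           sigma=sigma).fit(fixed=fixed)
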