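"""Synthetic cohort generation.

The downstream analyses assume a cohort in which each individual carries a
polygenic score (PGS), a binary or continuous trait value, a dichotomized
environmental exposure, and standard covariates.  This module generates
cohorts with exactly that statistical structure:

* the PGS is normally distributed (as expected for a sum of many small
  allelic effects);
* binary outcomes arise from a liability threshold model, where the latent
  liability is linear in PGS, environment, and optionally their product;
* continuous traits follow the exponential setpoint / modifiable-baseline /
  calibration-factor model ``trait = SP + MBL * exp(PGS / CF) + noise`` with
  environment-specific parameters;
* an optional genotype dosage panel supports allelic scoring and
  per-variant stratified effect-size experiments.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so each operation is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GenotypePanel",
    "COHORT_COLUMNS",
    "generate_pgs",
    "generate_covariates",
    "assign_environment",
    "simulate_binary_cohort",
    "simulate_continuous_cohort",
    "simulate_genotypes",
    "score_pgs",
]

#: canonical cohort column order (TSV interface)
COHORT_COLUMNS = [
    "individual_id", "pgs", "trait", "env",
    "age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5",
]

COVARIATE_NAMES = ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]


@dataclass
class SimulationConfig:
    """Parameters of the generative models.

    Liability model (binary traits)::

        L = a_env * PGS + b * Env + d * PGS * Env + N(0, 1)
        case  iff  L > t,   t set so the pooled case fraction = prevalence_target

    where ``a_env`` is ``a_low`` in the low stratum and ``a_high`` in the
    high stratum (``d`` adds a further interaction on top of any a_low/a_high
    difference).

    Exponential model (continuous traits)::

        trait = SP_env + MBL_env * exp(PGS / CF_env) + N(0, resid_sd^2)

    ``ge_corr`` induces a phenomenological correlation between the PGS and
    the probability of the high-risk exposure; it makes no mechanistic claim
    about why genotype and exposure co-vary.
    """

    n: int = 100_000
    prevalence_target: float = 0.1
    a_low: float = 0.5
    a_high: float = 0.5
    b: float = 0.0
    d: float = 0.0
    sp_low: float = 15.0
    sp_high: float = 15.0
    mbl_low: float = 12.0
    mbl_high: float = 12.0
    cf_low: float = 4.0
    cf_high: float = 4.0
    resid_sd: float = 1.0
    ge_corr: float = 0.0
    p_high: float = 0.5
    pgs_mean: float = 0.0
    pgs_sd: float = 1.0
    cov_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_high < 1.0):
            raise ValueError(f"p_high must lie in (0, 1), got {self.p_high}")
        if self.cf_low <= 0 or self.cf_high <= 0:
            raise ValueError("calibration factors cf_low/cf_high must be > 0")
        if self.mbl_low < 0 or self.mbl_high < 0:
            raise ValueError("modifiable baselines mbl_low/mbl_high must be >= 0")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")
        if not (0.0 < self.prevalence_target < 1.0):
            raise ValueError(
                f"prevalence_target must lie in (0, 1), got {self.prevalence_target}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenotypePanel:
    """Dosage matrix plus per-variant effect weights and allele frequencies."""

    dosages: np.ndarray          # (n, m), values in [0, 2]
    variant_ids: list[str]
    effect_weights: np.ndarray   # (m,)
    allele_freqs: np.ndarray     # (m,), in (0, 1)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.effect_weights = np.asarray(self.effect_weights, dtype=float)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        n, m = self.dosages.shape
        if not (len(self.variant_ids) == len(self.effect_weights)
                == len(self.allele_freqs) == m):
            raise ValueError("GenotypePanel dimensions are inconsistent")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if not np.all(np.isfinite(self.effect_weights)):
            raise ValueError("effect weights must be finite")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _spawn(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def generate_pgs(n: int, mean: float = 0.0, sd: float = 1.0,
                 seed=0) -> np.ndarray:
    """Draw ``n`` polygenic scores from Normal(mean, sd^2)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    return _rng(seed).normal(mean, sd, size=n)


def generate_covariates(n: int, seed=0) -> pd.DataFrame:
    """Age, sex and five genotype principal components, independent of PGS.

    Age ~ N(55, 8) years (a middle-aged volunteer cohort), sex ~ Bernoulli(0.5),
    PCs ~ N(0, 1).
    """
    rng = _rng(seed)
    out = pd.DataFrame({
        "age": rng.normal(55.0, 8.0, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
    })
    for k in range(1, 6):
        out[f"pc{k}"] = rng.normal(0.0, 1.0, size=n)
    return out


def assign_environment(pgs: np.ndarray, p_high: float = 0.5,
                       ge_corr: float = 0.0, seed=0) -> np.ndarray:
    """Assign each individual to the high-risk (1) or low-risk (0) exposure.

    ``ge_corr`` tilts the assignment probability linearly in the
    standardized PGS: P(env=1 | z) = p_high + ge_corr * z * sqrt(p_high *
    (1 - p_high)), clipped to [0, 1].  At ge_corr=0 assignment is
    independent of the PGS; positive values raise the mean PGS in the
    high-risk stratum, mimicking the slight PGS elevation seen in adverse
    exposures of observational cohorts.
    """
    if not (0.0 < p_high < 1.0):
        raise ValueError(f"p_high must lie in (0, 1), got {p_high}")
    if abs(ge_corr) >= 1.0:
        raise ValueError(f"|ge_corr| must be < 1, got {ge_corr}")
    pgs = np.asarray(pgs, dtype=float)
    sd = pgs.std()
    z = (pgs - pgs.mean()) / sd if sd > 0 else np.zeros_like(pgs)
    prob = p_high + ge_corr * z * np.sqrt(p_high * (1.0 - p_high))
    prob = np.clip(prob, 0.0, 1.0)
    return (_rng(seed).random(len(pgs)) < prob).astype(int)


def _assemble_cohort(pgs, trait, env, covs: pd.DataFrame) -> pd.DataFrame:
    n = len(pgs)
    table = pd.DataFrame({
        "individual_id": [f"ID{i:08d}" for i in range(n)],
        "pgs": np.asarray(pgs, dtype=float),
        "trait": np.asarray(trait, dtype=float),
        "env": np.asarray(env, dtype=int),
    })
    for c in COVARIATE_NAMES:
        table[c] = covs[c].to_numpy()
    return table[COHORT_COLUMNS]


def _covariate_shift(covs: pd.DataFrame, cov_effects: dict) -> np.ndarray:
    shift = np.zeros(len(covs))
    for name, beta in (cov_effects or {}).items():
        if name not in covs.columns:
            raise KeyError(f"unknown covariate in cov_effects: {name!r}")
        shift += beta * covs[name].to_numpy()
    return shift


def simulate_binary_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a case/control cohort under the liability threshold model.

    The liability is ``a_env*PGS + b*Env + d*PGS*Env + N(0,1)`` (plus any
    configured covariate effects); the case threshold is the empirical
    (1 - prevalence_target) quantile of the simulated pooled liability, so
    the realized pooled prevalence matches the target even when interaction
    terms skew the liability distribution.
    """
    seeds = _spawn(config.seed, 4)
    pgs = generate_pgs(config.n, config.pgs_mean, config.pgs_sd, seed=seeds[0])
    env = assign_environment(pgs, config.p_high, config.ge_corr, seed=seeds[1])
    covs = generate_covariates(config.n, seed=seeds[2])

    a_env = np.where(env == 1, config.a_high, config.a_low)
    liability = (
        a_env * pgs
        + config.b * env
        + config.d * pgs * env
        + _covariate_shift(covs, config.cov_effects)
        + _rng(seeds[3]).normal(0.0, 1.0, size=config.n)
    )
    t = np.quantile(liability, 1.0 - config.prevalence_target)
    trait = (liability > t).astype(float)
    return _assemble_cohort(pgs, trait, env, covs)


def simulate_continuous_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a quantitative-trait cohort from the exponential risk model."""
    seeds = _spawn(config.seed, 4)
    pgs = generate_pgs(config.n, config.pgs_mean, config.pgs_sd, seed=seeds[0])
    env = assign_environment(pgs, config.p_high, config.ge_corr, seed=seeds[1])
    covs = generate_covariates(config.n, seed=seeds[2])

    sp = np.where(env == 1, config.sp_high, config.sp_low)
    mbl = np.where(env == 1, config.mbl_high, config.mbl_low)
    cf = np.where(env == 1, config.cf_high, config.cf_low)
    trait = sp + mbl * np.exp(pgs / cf)
    trait = trait + _covariate_shift(covs, config.cov_effects)
    if config.resid_sd > 0:
        trait = trait + _rng(seeds[3]).normal(0.0, config.resid_sd, size=config.n)
    return _assemble_cohort(pgs, trait, env, covs)


def simulate_genotypes(n: int, m: int, maf_range=(0.05, 0.5),
                       effect_sd: float = 0.1, seed=0) -> GenotypePanel:
    """Simulate an unlinked dosage panel with normal effect weights.

    Dosages are Binomial(2, maf) per variant (Hardy-Weinberg, no LD);
    weights are N(0, effect_sd^2) on the log-odds / trait scale.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must be within (0, 0.5], got {maf_range}")
    rng = _rng(seed)
    mafs = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    weights = (rng.normal(0.0, effect_sd, size=m) if effect_sd > 0
               else np.zeros(m))
    ids = [f"rs{j:06d}" for j in range(m)]
    return GenotypePanel(dosages, ids, weights, mafs)


def score_pgs(panel: GenotypePanel) -> np.ndarray:
    """Additive allelic score: sum over variants of dosage * weight.

    The raw weighted allele sum (PLINK ``--score ... sum`` mode) is used
    rather than the per-allele average; only the ranking and the spread of
    the score matter downstream.
    """
    return panel.dosages @ panel.effect_weights
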