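# Methods

## Overview

`canalyzer` classifies trait–exposure pairs by comparing the divergence of
prevalence–risk (or trait-mean–risk) curves between two environmental
exposure strata at the extremes of polygenic risk with the divergence
expected from the overall environmental effect alone. The pipeline has four
stages: percentile curve construction, a permutation interaction screen, an
expected-deviation model (exponential for continuous traits, liability
threshold for binary traits), and departure scoring. A synthetic-cohort
generator provides the generative models the analysis assumes, so every
stage is testable end to end.

## Percentile curves and the delta statistic

Individuals are ranked by PGS on the **pooled** cohort (both strata
together) and split into 100 near-equal bins; pooling puts both curves on
one x-axis and enables the per-percentile high/low count-ratio analysis.
Ties take their average rank and are split stably. Within each bin ×
stratum the case fraction (binary) or trait mean (continuous) is recorded
with the bin's mean PGS and count. Empty bins are dropped from the H−L
difference rather than imputed; imputation would bias the permutation null.

The headline statistic **delta** is the right-tail minus left-tail H−L
deviation. Tail membership uses individual-level cutoffs at the pooled PGS
mean ± 2 SD (≈ the outer 2.3% tails for a normal PGS), not the outermost
percentile bins — finer than percentile resolution. Delta is invariant
under adding a constant to every trait value: a pure additive environmental
shift moves both tails equally and cancels.

## Interaction screen

Two conditions, both evaluated against 100 exposure-label permutations that
preserve stratum sizes (labels are reshuffled; pooled bins are fixed):

1. the smoothed derivative of H−L is consistently one-signed and its median
   exceeds in absolute value every permuted median;
2. the absolute linear slope of H−L exceeds every permuted slope.

Strict exceedance over all 100 permutations is an empirical one-sided
p < 1/101 per condition; requiring both is more conservative (measured
type-I rate ≤ ~2% across simulated null cohorts in the test suite).

Numerical choices: the per-percentile differences are smoothed with a
centered moving average (default window 11 bins) before differencing —
"consistently one-signed" is unattainable on raw binomial noise at
percentile resolution. "Consistently" is operationalized as ≥ 80% of
smoothed derivative values sharing the sign of their median
(`monotone_frac`, configurable). Before screening, the stratum with the
higher overall prevalence/mean is always relabeled "high"; this convention
makes signs comparable across exposures but can flip the intuitive reading
for some exposures (deprivation indices are the classic example).

Pairs failing the screen are classified: **additive shift** when the mean
H−L offset exceeds all permuted mean offsets without the slope conditions;
**nonmonotonic** when the smoothed derivative flips sign between the lower
and upper halves of the risk range with both half-medians outside the
permuted band (a symmetric hump has a near-zero linear slope, so the
half-range derivatives carry the signal — this criterion is this package's
own operationalization); **none** otherwise.

## Exponential risk model (continuous traits)

`Trait = SP + MBL · exp(PGS/CF) + ε`, PGS centered to median zero with
observed SD σ. Parameters: SP (setpoint; trait units; risk independent of
genetics), MBL (modifiable baseline; trait units; ≥ 0; the genetically
amplified component), CF (calibration factor; score units; > 0; larger CF =
weaker effective genetic modulation). The median prediction is SP + MBL.
The additive environmental deviation ε is absorbed into residual error; it
is never fitted as a separate term.

Because exp(PGS/CF) of a normal PGS is lognormal:

- E{Y} = SP + MBL·e^{σ²/2CF²}
- Var{Y} = MBL²(e^{2σ²/CF²} − e^{σ²/CF²})
- E{Y | PGS > kσ} = [SP·(1−Φ(k)) + MBL·(1−Φ(k−σ/CF))·e^{σ²/2CF²}]/(1−Φ(k))
- E{Y | PGS < −kσ} = [SP·Φ(−k) + MBL·Φ(−k−σ/CF)·e^{σ²/2CF²}]/Φ(−k)

The variance expression is the algebraic simplification of the expanded
form with SP cross-terms (the cross-terms cancel exactly; verified
symbolically and against Monte Carlo in the tests). The left-tail formula
is the exact truncated-lognormal conditional mean — the mirror image of the
right tail with lower-tail probabilities; both are validated against
quadrature to 1e-8.

Fitting is nonlinear least squares (trust-region reflective, analytic
Jacobian) with bounds MBL ≥ 0, CF ∈ [σ/50, 50σ], convergence tolerances
1e-12 (step/objective) and 1e-10 (gradient). Initialization: SP₀ = 5th
percentile of the outcome, MBL₀ = median − SP₀ (floored at 1e-3), CF₀ = σ —
this keeps the exponent near unity and the start feasible. Any parameter
can be held fixed (used for the constrained-MBL comparison). A CF driven to
its bound raises a warning and marks the fit non-converged; non-convergence
is always reported, never silently defaulted. Standard errors come from the
Gauss–Newton covariance (JᵀJ)⁻¹s²; interval coverage is calibrated in the
test suite at n = 100,000 (40 replicates, ≥ 85% required, ~93–95%
observed). Binary-trait curves are fitted at the percentile level (100
prevalence points weighted by bin counts); continuous traits at the
individual level.

### Continuous classification

Pipeline per pair: covariate adjustment (OLS residuals + grand mean) →
rank-based inverse normal transform (Blom offset 3/8, average ranks for
ties; configurable) → orient high = higher-mean stratum → fit low stratum
freely, fit high stratum with MBL fixed to the low estimate (so the curves
agree at median risk and only SP and CF shape the difference) → model-
implied delta from each stratum's closed-form tail means (each with its own
σ) → compare against 100 permutations of the **entire** pipeline (refit per
permutation; the null must reflect fitting variability). Decanalization if
delta exceeds all permuted deltas, canalization if below all, none
otherwise; non-converged fits yield an explicit `unclassifiable`, never a
silent none. The model-implied Var{Y} per stratum is reported as the
concordant criterion (delta and var_high − var_low agree in sign in
strong-effect simulations), and the raw-scale observed tail delta is
reported alongside without entering the classification.

A matched-prevalence utility dichotomizes a continuous trait at
stratum-specific cutoffs chosen to equalize case fractions, feeding the
binary pipeline as a cross-check.

## Liability threshold model (binary traits)

Within each percentile bin and stratum, liability is N(μᵢ, 1) with shared
threshold t = Φ⁻¹(1 − P_overall); observed prevalence gives
μᵢ = t − Φ⁻¹(1 − Pᵢ). OLS of μᵢ on (mean PGS, Env) over the ≤ 200 bin
points yields the null model; adding a PGS×Env term gives the interaction
model (which, by construction, absorbs genuine interaction — its expected
curves track the observed ones). Bins with prevalence exactly 0 or 1 have
infinite liability and are excluded from the regression (count logged);
they are retained when averaging prevalences over tail bins, where zero is
a valid value.

**Expected delta**: 10 iterations perturb the fitted μ̂ᵢ with N(0,
residual²) noise, convert to prevalences via 1 − Φ(t − μ), and recompute
the tail delta over bins whose mean PGS lies beyond the ±2σ cutoffs
(count-weighted, for comparability with the individual-level observed
delta). **Departure** = (delta_obs − mean delta_exp) / scale, where scale
is the mean expected-delta SD across the exposure battery for the trait
(single-exposure batteries fall back to their own SD with a logged
warning). Labels: |departure| ≥ 2 conservative, ≥ 1.3 suggestive; positive
= decanalization. Measured null rate of the conservative threshold is ≤ ~5%
per exposure in the test suite. A supplementary `ci_flag` marks observed
deltas outside mean ± 1.96 SD of the sampled expected-delta distribution;
it is reported alongside the label, not folded into it (error bars from
nonlinear-regression variance would be an alternative, but the sampling
band is fully specified by the model).

### Odds-ratio attenuation

Under the liability model, effect sizes estimated in a higher-prevalence
stratum are attenuated even with identical true liability effects — a
pattern that mimics canalization if uncorrected. `stratified_effect_sizes`
demonstrates this on simulated genotype panels: default estimator is the
2×2 effect-allele-count log-OR with Haldane–Anscombe 0.5 correction on zero
cells (deterministic and fast); per-variant logistic regression is
available via `method="logistic"`.

## Synthetic cohorts

The generator produces the structure the analysis assumes:

- PGS ~ N(0, 1) (score units; a weighted allele sum is a sum of many small
  effects). Genotype panels are unlinked Binomial(2, MAF) dosages with
  N(0, effect_sd²) weights, scored as the raw weighted sum (PLINK
  `--score ... sum` convention — only ranking and spread matter downstream).
- Binary traits: liability a_env·PGS + b·Env + d·PGS·Env + N(0,1), case
  threshold set to the empirical (1 − prevalence) quantile of the simulated
  pooled liability so the realized prevalence hits the target even when
  interaction skews the distribution. Defaults: a = 0.5 (a moderately
  predictive PGS, liability-R² ≈ 20%), prevalence 10–15% (common-disease
  range), b = 0.3 and d = 0.25 for "strong-effect" spike-ins.
- Continuous traits: SP_env + MBL_env·exp(PGS/CF_env) + N(0, resid_sd²),
  defaulting to the canonical BMI parameterization SP 15, MBL 12, CF 4,
  residual SD 1–2 trait units.
- `ge_corr` tilts P(env=1) linearly in the standardized PGS — a
  phenomenological stand-in for gene–environment correlation, making no
  claim about mechanism (reverse causation vs correlated directional
  effects are indistinguishable here).
- Covariates (age ~ N(55, 8), sex ~ Bernoulli(½), five PCs ~ N(0,1)) are
  generated independent of the PGS with configurable linear effects;
  observational cohorts confound them, so covariate-adjustment tests here
  only verify the adjustment machinery, not robustness to confounding.

All randomness flows from one seed through `SeedSequence` spawning; every
result is reproducible from (input, config, seed).

What the generator does **not** emulate — hence what passing tests cannot
show about real data: linkage disequilibrium and ascertainment in PGS
construction, non-normal PGS, exposure misclassification and
dichotomization error, family/shared-environment structure,
prevalence-dependent PGS miscalibration beyond the liability-model
attenuation itself, and missingness patterns.

## Problem sizes

Simulation-heavy checks are run at sizes chosen to make their statistical
targets meaningful: screen and departure calibration at n = 20,000 per
cohort (50 cohorts / 10 batteries × 8 exposures), parameter-interval
coverage at n = 100,000 × 40 replicates, spike-in screens at n = 100,000 –
500,000 (the screen's strict all-permutation exceedance needs large n for
moderate interaction terms), and constrained-MBL recovery at n = 20,000 ×
10 replicates. Closed forms are checked against 10⁷-draw Monte Carlo and
adaptive quadrature.

## Known limitations

- The pooled inverse normal transform is not exactly shift-invariant: a
  large pure setpoint shift (≳ 0.5 trait SD) warps the two strata's shapes
  in rank space and can push the constrained-MBL delta slightly negative
  (toward the canalization side). Modest shifts stay inside the permutation
  band; the screen's additive-shift class catches the pattern first.
- Strict all-exceedance over 100 permutations saturates at p ≈ 0.01;
  stronger evidence requires more permutations (`n_perm`).
- The liability regression treats bin mean PGS as exact; at very small
  strata the errors-in-variables effect biases the slope downward.
- `scale_sd` for a single-exposure battery is that exposure's own expected
  SD, which the battery-mean rule was designed to stabilize; single-pair
  departures are accordingly noisier.
- Classification depends on the elevated-risk orientation convention;
  canalization with respect to one exposure is decanalization with respect
  to its complement.
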