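"""End-to-end binary and continuous trait-exposure pipelines.

A "battery" is a set of exposures analyzed against one trait.  For binary
traits the departure statistic is scaled by the mean expected-delta SD
across the whole battery (more stable than each exposure's own SD); the
battery therefore has to be processed together.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .continuous import continuous_canalization
from .io import RunConfig
from .liability import analyze_binary_pair, departure_score
from .screen import screen_pgsxe

logger = logging.getLogger("canalyzer")

__all__ = ["run_binary_pipeline", "run_continuous_pipeline"]


def _pair_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index])
               .generate_state(1)[0] % (2 ** 31))


def run_binary_pipeline(cohorts: dict, config: RunConfig | None = None
                        ) -> pd.DataFrame:
    """Screen and classify a battery of binary trait-exposure cohorts.

    ``cohorts`` maps ``(trait_name, exposure_name)`` to a cohort table.
    Per pair: the permutation screen runs first; the liability machinery
    then yields observed and expected tail deltas; departures are scaled by
    the battery-mean expected SD per trait and labeled at the conservative
    (2 SD) and suggestive (1.3 SD) thresholds.  Failures in one pair are
    recorded and the run continues.
    """
    config = config or RunConfig()
    interim = []
    for idx, ((trait, exposure), cohort) in enumerate(sorted(cohorts.items())):
        seed = _pair_seed(config.seed, idx)
        row = {"trait": trait, "exposure": exposure, "error": ""}
        try:
            screen = screen_pgsxe(
                cohort, n_perm=config.n_perm, n_bins=config.n_bins,
                window=config.window, seed=seed,
                monotone_frac=config.monotone_frac)
            row.update(screen.to_record())
            pair = analyze_binary_pair(
                cohort, n_bins=config.n_bins,
                n_iter=config.n_iter_expected, sd_mult=config.sd_mult,
                seed=seed + 1)
            row.update({
                "delta_obs": pair["observed"].delta,
                "delta_exp_mean": pair["delta_exp_mean"],
                "delta_exp_sd": pair["delta_exp_sd"],
                "ci_flag": pair["ci_flag"],
                "interaction_d": pair["fit_interaction"].d,
                "null_residual_sd": pair["fit_null"].residual_sd,
            })
        except (ValueError, RuntimeError) as err:
            row["error"] = str(err)
            logger.warning("pair (%s, %s) failed: %s", trait, exposure, err)
        interim.append(row)

    results = pd.DataFrame(interim)
    if results.empty:
        return results
    # battery-level scale: mean expected-delta SD across exposures per trait
    results["departure"] = np.nan
    results["label"] = "error"
    if "delta_exp_sd" in results.columns:
        for trait, group in results.groupby("trait"):
            ok = group["error"] == ""
            if not ok.any():
                continue
            scale_sd = float(group.loc[ok, "delta_exp_sd"].mean())
            if ok.sum() == 1:
                logger.warning(
                    "trait %r has a single exposure; departure scaled by its "
                    "own expected-delta SD", trait)
            if not scale_sd > 0:
                logger.warning("trait %r: zero expected-delta scale; "
                               "departures undefined", trait)
                continue
            for i in group.index[ok]:
                res = departure_score(
                    results.at[i, "delta_obs"],
                    results.at[i, "delta_exp_mean"], scale_sd,
                    delta_exp_sd=results.at[i, "delta_exp_sd"],
                    conservative=config.conservative_threshold,
                    suggestive=config.suggestive_threshold,
                    ci_flag=bool(results.at[i, "ci_flag"]))
                results.at[i, "departure"] = res.departure
                results.at[i, "label"] = res.label
    results.attrs["config_hash"] = config.config_hash
    return results


def run_continuous_pipeline(cohorts: dict, config: RunConfig | None = None
                            ) -> pd.DataFrame:
    """Classify a battery of continuous trait-exposure cohorts.

    Per pair: covariate adjustment, inverse normal transform, constrained-
    MBL exponential fits, model-implied tail delta versus 100 label
    permutations; output is a ranked delta table with per-pair labels and
    the model-implied variances.
    """
    config = config or RunConfig()
    rows = []
    for idx, ((trait, exposure), cohort) in enumerate(sorted(cohorts.items())):
        seed = _pair_seed(config.seed, idx)
        row = {"trait": trait, "exposure": exposure, "error": ""}
        try:
            res = continuous_canalization(
                cohort, n_perm=config.n_perm, sd_mult=config.sd_mult,
                seed=seed, int_offset=config.int_offset)
            row.update({
                "delta_int": res.delta_obs_int,
                "delta_raw": res.delta_obs_raw,
                "var_high": res.var_high,
                "var_low": res.var_low,
                "high_env": res.high_env,
                "label": res.label,
            })
        except (ValueError, RuntimeError) as err:
            row["error"] = str(err)
            row["label"] = "error"
            logger.warning("pair (%s, %s) failed: %s", trait, exposure, err)
        rows.append(row)
    results = pd.DataFrame(rows)
    if not results.empty and "delta_int" in results.columns:
        results = results.sort_values(
            "delta_int", ascending=False, na_position="last"
        ).reset_index(drop=True)
    results.attrs["config_hash"] = config.config_hash
    return results
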