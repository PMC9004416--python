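"""Cohort/weight-file I/O, run configuration and structured logging."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .simulate import COHORT_COLUMNS

logger = logging.getLogger("canalyzer")

__all__ = ["RunConfig", "read_cohort", "write_cohort", "read_weights",
           "read_config"]

REQUIRED_COLUMNS = ["individual_id", "pgs", "trait", "env"]


@dataclass
class RunConfig:
    """Knobs shared by the screening and classification stages.

    Defaults follow the analysis conventions: 100 percentile bins, 100
    label permutations, 10 sampling iterations for the expected delta,
    tails at 2 SD from the PGS mean, conservative/suggestive departure
    thresholds of 2 and 1.3 SD units, an 11-bin smoothing window for the
    H-L derivative, and the Blom offset 0.375 for the inverse normal
    transform.
    """

    n_bins: int = 100
    n_perm: int = 100
    n_iter_expected: int = 10
    sd_mult: float = 2.0
    conservative_threshold: float = 2.0
    suggestive_threshold: float = 1.3
    window: int = 11
    monotone_frac: float = 0.8
    int_offset: float = 0.375
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conservative_threshold <= 0 or self.suggestive_threshold <= 0:
            raise ValueError("departure thresholds must be positive")
        if self.suggestive_threshold >= self.conservative_threshold:
            raise ValueError("suggestive threshold must be below the "
                             "conservative one")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        logger.info("run config loaded: %s",
                    json.dumps(cfg.to_dict(), sort_keys=True))
        return cfg


def read_config(path) -> RunConfig:
    return RunConfig.from_file(path)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort TSV.

    Rows with missing pgs, trait or env are dropped with a logged count
    (mirroring the exclusion of non-responses in survey data); the env
    column must take exactly two values, recoded to {0, 1} if needed.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks required column(s): "
                         f"{missing}")
    n_in = len(table)
    table = table.dropna(subset=["pgs", "trait", "env"])
    n_dropped = n_in - len(table)
    if n_dropped:
        logger.warning("dropped %d of %d rows with missing pgs/trait/env",
                       n_dropped, n_in)
    if table["individual_id"].duplicated().any():
        dupes = table.loc[table["individual_id"].duplicated(),
                          "individual_id"].head(3).tolist()
        raise ValueError(f"duplicated individual_id values, e.g. {dupes}")
    levels = sorted(table["env"].unique())
    if len(levels) != 2:
        raise ValueError(f"env must take exactly two values, found {levels}")
    if levels != [0, 1]:
        table = table.assign(env=(table["env"] == levels[1]).astype(int))
        logger.info("env recoded: %s->0, %s->1", levels[0], levels[1])
    else:
        table = table.assign(env=table["env"].astype(int))
    if not np.isfinite(table["pgs"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite PGS values present")
    return table.reset_index(drop=True)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, sep="\t", index=False)


def read_weights(path) -> pd.DataFrame:
    """Read a 3-column whitespace-delimited allelic weight file.

    Columns: variant_id, effect_allele, beta (the PLINK ``--score`` input
    dialect).  Duplicate variant ids and non-numeric betas are rejected
    with the offending id / line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and parts[0].lower() in {"variant_id", "snp", "id"}:
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, "
                                 f"got {len(parts)}")
            vid, allele, beta = parts
            try:
                beta = float(beta)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric beta "
                                 f"{parts[2]!r}") from None
            rows.append((vid, allele, beta))
    table = pd.DataFrame(rows, columns=["variant_id", "effect_allele", "beta"])
    dupes = table.loc[table["variant_id"].duplicated(), "variant_id"]
    if len(dupes):
        raise ValueError(f"duplicate variant id(s): "
                         f"{sorted(set(dupes))[:3]}")
    return table
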