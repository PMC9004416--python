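import numpy as np
import pytest

from canalyzer import SimulationConfig, simulate_binary_cohort, \
    simulate_continuous_cohort


@pytest.fixture(scope="session")
def null_binary_cohort():
    """No genetic-by-environment structure beyond a main PGS effect."""
    cfg = SimulationConfig(n=60_000, a_low=0.5, a_high=0.5, b=0.0, d=0.0,
                           prevalence_target=0.15, seed=101)
    return simulate_binary_cohort(cfg)


@pytest.fixture(scope="session")
def interaction_binary_cohort():
    """Positive PGS-by-environment liability interaction."""
    cfg = SimulationConfig(n=200_000, a_low=0.5, a_high=0.5, b=0.3, d=0.25,
                           prevalence_target=0.15, seed=102)
    return simulate_binary_cohort(cfg)


@pytest.fixture(scope="session")
def null_continuous_cohort():
    cfg = SimulationConfig(n=30_000, resid_sd=2.0, seed=103)
    return simulate_continuous_cohort(cfg)


@pytest.fixture(scope="session")
def cf_amplified_cohort():
    """High stratum has amplified genetic modulation (smaller CF)."""
    cfg = SimulationConfig(n=30_000, cf_low=4.0, cf_high=2.5, resid_sd=2.0,
                           seed=104)
    return simulate_continuous_cohort(cfg)
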