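"""Shared fixtures: synthetic cohorts and desk-scale hierarchical fits.

The expensive MCMC fits are session-scoped so recovery, model-selection
and summary tests share them.
"""

import numpy as np
import pytest
from hypothesis import settings

import forcematch as fm

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

#: Generating truth used by the recovery fixtures (population mean
#: attenuation factor 1.6, half-normal scale 0.15 for its trial-to-trial SD).
RECOVERY_POP = fm.PopulationTruth(mean_K_mean=1.6, mean_K_sd=0.2, sd_K_scale=0.15)
SUBTRACTIVE_POP = fm.PopulationTruth(mean_K_mean=1.3, mean_K_sd=0.3, sd_K_scale=0.15)

COHORT_SEED = 1
N_RECOVERY = 20


@pytest.fixture(scope="session")
def study1_design():
    return fm.DESIGN_PRESETS["study1"]


@pytest.fixture(scope="session")
def divisive_cohort(study1_design):
    """20 participants simulated from the divisive model (with truth)."""
    return fm.simulate_study(
        RECOVERY_POP, study1_design, "divisive", N_RECOVERY, seed=COHORT_SEED
    )


@pytest.fixture(scope="session")
def subtractive_cohort(study1_design):
    return fm.simulate_study(
        SUBTRACTIVE_POP, study1_design, "subtractive", N_RECOVERY, seed=COHORT_SEED
    )


@pytest.fixture(scope="session")
def desk_config():
    return fm.MCMCConfig.desk(seed=0)


@pytest.fixture(scope="session")
def divisive_fit(divisive_cohort, desk_config):
    """Divisive model fitted to divisive-generated data."""
    return fm.fit(divisive_cohort[0], "divisive", desk_config)


@pytest.fixture(scope="session")
def divisive_fit_subtractive_model(divisive_cohort, desk_config):
    return fm.fit(divisive_cohort[0], "subtractive", desk_config)


@pytest.fixture(scope="session")
def subtractive_fit(subtractive_cohort, desk_config):
    return fm.fit(subtractive_cohort[0], "subtractive", desk_config)


@pytest.fixture(scope="session")
def subtractive_fit_divisive_model(subtractive_cohort, desk_config):
    return fm.fit(subtractive_cohort[0], "divisive", desk_config)
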