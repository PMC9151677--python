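import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import settings

from craftct.cohort import CohortConfig, build_feature_table, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def study_config() -> CohortConfig:
    """Calibrated patient-cohort config at a size small enough for unit tests."""
    return CohortConfig.default_study(n_subjects=300, seed=11)


@pytest.fixture(scope="session")
def clean_config(study_config) -> CohortConfig:
    """Same study, but noise-free and without missingness or exclusions."""
    return dataclasses.replace(
        study_config,
        noise_sd=0.0,
        missing_rate_weight=0.0,
        missing_rate_stature=0.0,
        frac_nonsteady=0.0,
        frac_repeat_near=0.0,
        frac_repeat_far=0.0,
        frac_two_collections=0.0,
    )


@pytest.fixture(scope="session")
def study_cohort(study_config):
    records, truth = generate_cohort(study_config)
    return records, truth


@pytest.fixture(scope="session")
def study_table(study_cohort):
    records, truth = study_cohort
    return build_feature_table(records), truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
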