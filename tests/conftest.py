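import numpy as np
import pytest

from netlie import CohortConfig, StudyConfig, generate_cohort


@pytest.fixture(scope="session")
def small_study_config() -> StudyConfig:
    """A reduced but structurally complete study: 14 subjects, light null model."""
    return StudyConfig(
        n_random=5,
        seed=42,
        n_subjects=14,
        cohort=CohortConfig(n_liars=9),
    )


@pytest.fixture(scope="session")
def small_cohort(small_study_config):
    return generate_cohort(
        small_study_config.n_subjects, small_study_config.cohort, seed=small_study_config.seed
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
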