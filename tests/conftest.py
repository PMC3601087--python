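import numpy as np
import pytest

from gmtraj.synth import (
    CohortConfig,
    default_abstinence_effect,
    generate_covariates,
    generate_gm_maps,
)


@pytest.fixture(scope="session")
def tiny_config():
    """Small noiseless phantom for closed-form checks."""
    return CohortConfig(
        n_cd=12,
        n_ctrl=12,
        grid_shape=(20, 24, 20),
        noise_sd=0.0,
        effects=(
            dict(center_voxel=(10, 12, 10), radius_mm=6.0, term="abstinence_weeks",
                 slope=0.002, cd_offset=-0.05),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    cohort = generate_covariates(tiny_config)
    maps, truth = generate_gm_maps(cohort, tiny_config)
    return cohort, maps, truth


@pytest.fixture(scope="session")
def study_config():
    """Study-scale phantom: 43+43 subjects, one abstinence effect, noisy."""
    return CohortConfig(effects=(default_abstinence_effect(),), seed=5)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    cohort = generate_covariates(study_config)
    maps, truth = generate_gm_maps(cohort, study_config)
    return cohort, maps, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
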