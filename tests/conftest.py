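import dataclasses

import pytest

from rras2kit.config import CohortConfig


@pytest.fixture
def small_config() -> CohortConfig:
    """A quick study-shaped cohort for integration tests."""
    return CohortConfig(n_healthy=60, n_patient_blood=50, n_tumor=90, seed=7)


@pytest.fixture
def noise_free_config() -> CohortConfig:
    """All noise terms zero: downstream estimators must recover truth exactly."""
    return CohortConfig(
        n_healthy=40,
        n_patient_blood=30,
        n_tumor=60,
        plate_effect_sd=0.0,
        ct_noise_sd=0.0,
        fluor_noise_cv=0.0,
        template_amount_cv=0.0,
        expr_biological_sd=0.0,
        expr_log2fc_base=0.0,
        seed=11,
    )


def with_overrides(config: CohortConfig, **kwargs) -> CohortConfig:
    return dataclasses.replace(config, **kwargs)
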