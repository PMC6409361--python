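"""Shared fixtures: small synthetic cohorts sized for fast unit tests."""

import pytest

from absig import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        n_subjects=120,
        n_validation=40,
        n_protein_analytes=12,
        n_metabolite_analytes=6,
        missing_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def training_cohort(small_cohort):
    from absig import split_cohorts

    training, _ = split_cohorts(small_cohort)
    return training


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()
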