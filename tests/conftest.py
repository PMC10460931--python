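"""Shared fixtures: worked-example cohorts reproducing the published
validation cohort tables, and a reusable synthetic cohort."""

import pytest

from pmvalidate import GeneratorConfig, generate_cohort
from pmvalidate.examples import infection_validation_cohort, pneumonia_validation_cohort


@pytest.fixture(scope="session")
def pneumonia_table_cohort():
    return pneumonia_validation_cohort()


@pytest.fixture(scope="session")
def infection_table_cohort():
    return infection_validation_cohort()


@pytest.fixture(scope="session")
def default_cohort_50k():
    """One complete 50,000-admission synthetic cohort at the default
    prevalences, shared across prevalence-fidelity checks."""
    return generate_cohort(GeneratorConfig(n=50_000, seed=424242))
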