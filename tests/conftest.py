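"""Shared fixtures: small synthetic cohorts and stacked datasets."""

import numpy as np
import pytest

from tivae.preprocessing import stack_tissues
from tivae.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(
        n_tissues=3,
        n_individuals=40,
        n_cases=26,
        universe_size=120,
        genes_per_tissue=60,
        signature_genes_per_tissue=8,
        diff_genes_per_tissue=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_stacked(small_cohort):
    return stack_tissues(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
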