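import numpy as np
import pytest

from genesieve.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small strong-signal cohort with 10% mislabeled cases, shared across tests."""
    cfg = CohortConfig(
        n_cases=300,
        n_controls=300,
        n_variants=100,
        n_genes=30,
        n_causal_genes=10,
        effect_sd=1.0,
        case_flip_rate=0.10,
        seed=1,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no genetic effect on the phenotype and no label noise."""
    cfg = CohortConfig(
        n_cases=400,
        n_controls=400,
        n_variants=200,
        n_genes=60,
        n_causal_genes=10,
        effect_sd=0.0,
        case_flip_rate=0.0,
        seed=3,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
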