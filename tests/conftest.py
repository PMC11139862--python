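import numpy as np
import pytest

from sepsispatterns import SyntheticCohortConfig, generate_cohort

from helpers import make_expression


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free small cohort with full sampling (no dropout)."""
    cfg = SyntheticCohortConfig(
        n_sepsis_subjects=24, n_healthy=10, outcome_counts=(12, 10, 2),
        n_genes=150, K_true=3, noise_kind="none", dropout=False, seed=7)
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-shaped (but smaller) cohort with log-normal noise and dropout."""
    cfg = SyntheticCohortConfig(
        n_sepsis_subjects=40, n_healthy=12, outcome_counts=(20, 16, 4),
        n_genes=300, K_true=4, noise_sigma=0.15, seed=11)
    return generate_cohort(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def expr_factory():
    return make_expression
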