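import warnings

import numpy as np
import pytest

from moclust import GeneratorConfig, fit_factor_model, generate_multiomics_cohort

# the factor fits in these tests intentionally run to the sweep cap
warnings.filterwarnings("ignore", message="factor model .* did not converge")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down cohort for fast unit tests (structure preserved)."""
    return GeneratorConfig(n_samples=150, k_total=8, k_prognostic=3,
                           n_features=(400, 60, 12),
                           missing_fractions=(0.08, 0.06, 0.3), seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_multiomics_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the full study conditions."""
    return generate_multiomics_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_model(small_cohort):
    dataset, _ = small_cohort
    return fit_factor_model(dataset, K=8, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
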