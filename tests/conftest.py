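import numpy as np
import pytest

from pdresnet import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (457 subjects x 194 features)."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def small_cohort_config():
    """A fast cohort for pipeline tests: 40 PD (30 early / 10 mod-adv) + 24 HC."""
    return CohortConfig(n_pd=40, n_hc=24, n_early=30, n_modadv=10,
                        effect_size=1.5, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return generate_cohort(small_cohort_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
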