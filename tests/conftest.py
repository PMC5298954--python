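import numpy as np
import pytest

from timepref import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_subjects=100, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def binomial_band(p, n, level=0.99):
    """Half-width of a normal-approximation confidence band for a proportion."""
    from scipy import stats
    z = stats.norm.ppf(0.5 + level / 2)
    return z * np.sqrt(p * (1 - p) / n)
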