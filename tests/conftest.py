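import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from pnrcount import MixtureParams, PhotonHistogram, SimConfig, sample_histogram

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def theta_one() -> MixtureParams:
    return MixtureParams.from_flat([8, 0.1])


@pytest.fixture(scope="session")
def theta_two() -> MixtureParams:
    return MixtureParams.from_flat([8, 0.1, 10, 0.2])


@pytest.fixture(scope="session")
def theta_three() -> MixtureParams:
    return MixtureParams.from_flat([8, 0.1, 10, 0.2, 12, 0.3])


@pytest.fixture(scope="session")
def hist_one_1e5(theta_one) -> PhotonHistogram:
    """A mid-size single-species histogram shared across estimator tests."""
    return sample_histogram(SimConfig(theta=theta_one, nu=10**5, seed=42))


def random_mixture(rng: np.random.Generator, m: int, M_max: int = 12) -> MixtureParams:
    """Random valid mixture for property tests (p bounded away from 0/1)."""
    flat = []
    for _ in range(m):
        flat += [int(rng.integers(1, M_max + 1)), float(rng.uniform(0.05, 0.95))]
    return MixtureParams.from_flat(flat)
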