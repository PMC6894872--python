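import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mvextrap import compute_measures, fit, make_fixture
from mvextrap.mvn_gibbs import McmcSettings, Priors

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def random_spd(n: int, rng: np.random.Generator, jitter: float = 0.5) -> np.ndarray:
    """Well-conditioned random symmetric positive definite matrix."""
    A = rng.standard_normal((n, n))
    return A @ A.T + jitter * n * np.eye(n)


@pytest.fixture(scope="session")
def tiny():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_fit(tiny):
    draws = fit(tiny.data, Priors(), McmcSettings(iterations=800, seed=7))
    return tiny, draws


@pytest.fixture(scope="session")
def lagos():
    return make_fixture("lagos-like")


@pytest.fixture(scope="session")
def lagos_fit(lagos):
    draws = fit(lagos.data, Priors(), McmcSettings(iterations=1500, seed=2))
    return lagos, draws


@pytest.fixture(scope="session")
def lagos_det(lagos_fit):
    ds, draws = lagos_fit
    return compute_measures(draws, ds.data, "mvpv_det")
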