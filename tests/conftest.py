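import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured synthetic dataset shared across tests."""
    from wingcline import SimulationConfig, simulate

    return simulate(
        SimulationConfig(
            sites_per_transect=(3, 3, 2),
            apiaries_per_site=2,
            colonies_per_apiary=2,
            wings_per_colony=3,
            n_loci=60,
            seed=7,
        )
    )


def random_shape(rng, k=19, scale=1.0):
    return rng.normal(0.0, scale, (k, 2))


def random_similarity(rng, shape):
    """Apply a random rotation, positive scale, and translation."""
    ang = rng.uniform(0, 2 * np.pi)
    r = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
    s = np.exp(rng.normal(0, 1))
    t = rng.normal(0, 10, 2)
    return shape @ r * s + t
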