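import numpy as np
import pytest

from atlas import SimulationTruth, generate_domain
from atlas.simulate import simulate_study


@pytest.fixture(scope="session")
def domain_200km():
    """A 200 km × 200 km domain tiled by 16 districts of 50 km."""
    return generate_domain(4, 4, 50.0)


@pytest.fixture(scope="session")
def small_study(domain_200km):
    """A modest synthetic study shared by read-only tests."""
    truth = SimulationTruth.from_range(beta=(-1.0, 0.5, -0.3), sigma2_omega=0.5,
                                       range_km=40.0, sigma2_eps=0.0, seed=20)
    clusters, grids = simulate_study(domain_200km, 200, truth, smoothness_km=25.0)
    return {"domain": domain_200km, "truth": truth, "clusters": clusters, "grids": grids}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
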