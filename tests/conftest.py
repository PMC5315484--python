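import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mixotroph import Environment, ModelParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20160802)


def random_traits(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform samples from the feasible simplex sum(phi) <= 1 (rows L, F, N)."""
    # Dirichlet over (phi_L, phi_F, phi_N, slack) gives uniform simplex interior
    return rng.dirichlet(np.ones(4), size=n)[:, :3]


def random_envs(rng: np.random.Generator, n: int) -> list[Environment]:
    X_L = 10 ** rng.uniform(0.0, 2.8, n)      # ~1 .. 630 umol photons
    X_N = 10 ** rng.uniform(-1.0, 2.5, n)     # ~0.1 .. 316 ug N/L
    X_F = 10 ** rng.uniform(0.0, 3.3, n)      # ~1 .. 2000 ug C/L
    return [Environment(float(a), float(b), float(c)) for a, b, c in zip(X_L, X_N, X_F)]
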