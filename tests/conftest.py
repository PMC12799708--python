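import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from copolymer import RateParameters

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def near_critical_params() -> RateParameters:
    """Two-monomer set with alpha ~ 1.0185: barely transient, slow mixing."""
    return RateParameters(kplus=(1.0, 1.2), kminus=(1.8, 2.592))


@pytest.fixture
def strong_params() -> RateParameters:
    """Strongly transient two-monomer set: alpha = 6, m = v = 2.5, sigma = (2/3, 1/3)."""
    return RateParameters(kplus=(2.0, 1.0), kminus=(0.5, 0.5))


@pytest.fixture
def recurrent_params() -> RateParameters:
    """Positive-recurrent set: alpha = 0.5, root occupancy 1 - alpha = 0.5."""
    return RateParameters(kplus=(1.0, 1.0), kminus=(4.0, 4.0))


@pytest.fixture
def birth_death_params() -> RateParameters:
    """d = 1 biased walk: m = 2, F = 1/3, v_bar = 1/2."""
    return RateParameters(kplus=(3.0,), kminus=(1.0,))


def random_transient_params(rng: np.random.Generator, d: int | None = None) -> RateParameters:
    """One random parameter draw conditioned on transience (alpha > 1)."""
    if d is None:
        d = int(rng.integers(1, 6))
    while True:
        kplus = np.exp(rng.uniform(np.log(0.1), np.log(10.0), size=d))
        kminus = np.exp(rng.uniform(np.log(0.1), np.log(10.0), size=d))
        if np.sum(kplus / kminus) > 1.0 + 1e-6:
            return RateParameters(kplus=tuple(kplus), kminus=tuple(kminus))
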