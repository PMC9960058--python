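import numpy as np
import pytest

from casekin import EnzymeSetting, RateConstants, species_closed_form

#: Model constants at the reference enzyme concentration 0.25 mg/L:
#: k1*E0 = 0.0066 s^-1, k2 = 0.0015 s^-1, k3*E0 = 0.0002 s^-1.
REF_K1E0 = 0.0066
REF_K2 = 0.0015
REF_K3E0 = 0.0002
REF_E0 = 0.25


@pytest.fixture(scope="session")
def ref_rates() -> RateConstants:
    return RateConstants.from_effective(
        k1E0=REF_K1E0, k2=REF_K2, k3E0=REF_K3E0, E0=REF_E0
    )


@pytest.fixture(scope="session")
def ref_env() -> EnzymeSetting:
    return EnzymeSetting(E0=REF_E0)


@pytest.fixture(scope="session")
def time_grid() -> np.ndarray:
    return np.linspace(0.0, 1e4, 2001)


@pytest.fixture(scope="session")
def ref_trajectory(ref_rates, ref_env, time_grid):
    return species_closed_form(ref_rates, ref_env, time_grid)


def random_distinct_rates(rng: np.random.Generator):
    """Three effective rates in [1e-5, 1e-1] s^-1, pairwise distinct by
    construction (log-uniform draws, retried on near-coincidence)."""
    while True:
        a, b, c = 10 ** rng.uniform(-5, -1, size=3)
        pairs = ((a, b), (a, c), (b, c))
        if all(abs(u - v) > 1e-6 * max(u, v) for u, v in pairs):
            return a, b, c
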