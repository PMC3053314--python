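import numpy as np
import pytest

from channoise.kinetics import ChannelScheme, SubunitSpec
from channoise.rates import RatePair, constant_rate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def k_scheme():
    from channoise.fixtures import potassium_scheme

    return potassium_scheme()


@pytest.fixture(scope="session")
def na_scheme():
    from channoise.fixtures import sodium_scheme

    return sodium_scheme()


@pytest.fixture(scope="session")
def small_fixture():
    """10x10 um cell: small enough for visible channel noise, cheap to run."""
    from channoise.fixtures import build_hh_fixture

    return build_hh_fixture(length_um=10.0, diameter_um=10.0)


def two_state_scheme(alpha: float, beta: float) -> ChannelScheme:
    """Single 2-state gate with constant rates (per ms)."""
    return ChannelScheme.from_subunits(
        "two_state",
        [SubunitSpec("x", 1, RatePair(constant_rate(alpha), constant_rate(beta)))],
    )
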