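import warnings

import pytest
from hypothesis import HealthCheck, settings

import neuronotch as nn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cheb_model():
    return nn.build_channel("chebyshev", 60)


@pytest.fixture(scope="session")
def bessel_model():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", nn.DesignCaveatWarning)
        return nn.build_channel("bessel", 60)


@pytest.fixture(scope="session")
def no_notch_model():
    return nn.build_channel("no_notch", 60)


@pytest.fixture(scope="session")
def cheb_digital(cheb_model):
    return nn.discretize(cheb_model, 20_000.0)


@pytest.fixture(scope="session")
def bessel_digital(bessel_model):
    return nn.discretize(bessel_model, 20_000.0)
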