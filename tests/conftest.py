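import numpy as np
import pytest

from rmfilter.systems import (LinearGaussianSystem, TimeDiscretization,
                              builtin_fixture)


@pytest.fixture(scope="session")
def system1() -> LinearGaussianSystem:
    return builtin_fixture("system1")


@pytest.fixture(scope="session")
def system2() -> LinearGaussianSystem:
    return builtin_fixture("system2")


@pytest.fixture(scope="session")
def fig1_example():
    return builtin_fixture("fig1")


@pytest.fixture
def tgrid_fast() -> TimeDiscretization:
    return TimeDiscretization(T=1.0, dt=1e-3, delta_d=1e-2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240241)
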