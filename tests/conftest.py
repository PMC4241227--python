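import numpy as np
import pytest

import intflux as ifx


@pytest.fixture(scope="session")
def branched():
    """Branched GMA benchmark: (model, p_true, X0)."""
    return ifx.branched_fixture()


@pytest.fixture(scope="session")
def toy_gma():
    return ifx.toy_gma_fixture()


@pytest.fixture(scope="session")
def toy_linlog():
    return ifx.toy_linlog_fixture()


@pytest.fixture(scope="session")
def lactis():
    return ifx.lactis_linlog_fixture()


@pytest.fixture(scope="session")
def toy_gma_data(toy_gma):
    """Noise-free toy GMA dataset, 60 uniform points over the transient."""
    model, p_true, X0 = toy_gma
    times = np.linspace(0.0, 8.0, 60)
    return ifx.generate_dataset(model, p_true, X0, times)


@pytest.fixture(scope="session")
def branched_data(branched):
    """Noise-free branched dataset on the default 50-point grid."""
    model, p_true, X0 = branched
    return ifx.generate_dataset(model, p_true, X0, ifx.default_times("branched"))


@pytest.fixture(scope="session")
def toy_linlog_data(toy_linlog):
    model, p_true, X0 = toy_linlog
    times = np.linspace(0.0, 6.0, 50)
    return ifx.generate_dataset(model, p_true, X0, times)
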