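import pytest

from chondrosim import (
    HealthSpec,
    OsmoticParameters,
    TissueParameters,
    steady_state,
)


@pytest.fixture(scope="session")
def osmo():
    return OsmoticParameters()


@pytest.fixture(scope="session")
def params():
    return TissueParameters()


@pytest.fixture(scope="session")
def health_spec():
    return HealthSpec()


@pytest.fixture(scope="session")
def medium_quasi_steady(params, osmo):
    """Quasi-stationary tissue state under the deterministic medium load."""
    return steady_state(params, osmo, mean_stress=350.0, mean_frequency=0.1)
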