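import numpy as np
import pytest

from fontansim import (
    build_topology,
    default_parameters,
    run_to_steady_state,
    summarize,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def bcpa_topology(params):
    return build_topology("BCPA", params)


@pytest.fixture(scope="session")
def tcpc_topology(params):
    return build_topology("TCPC", params)


@pytest.fixture(scope="session")
def bcpa_result(bcpa_topology, params):
    return run_to_steady_state(bcpa_topology, params, tol=1e-6, max_cycles=800)


@pytest.fixture(scope="session")
def tcpc_result(tcpc_topology, params):
    return run_to_steady_state(tcpc_topology, params, tol=1e-6, max_cycles=800)


@pytest.fixture(scope="session")
def bcpa_summary(bcpa_result, params):
    return summarize(bcpa_result, params)


@pytest.fixture(scope="session")
def tcpc_summary(tcpc_result, params):
    return summarize(tcpc_result, params)
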