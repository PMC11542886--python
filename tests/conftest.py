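import numpy as np
import pytest

from anaerobead import (AnalysisTables, KineticParameterSet,
                        assemble_system,
                        integrate_to_steady_state, make_influent,
                        make_toy_system)


@pytest.fixture(scope="session")
def params():
    return KineticParameterSet()


@pytest.fixture(scope="session")
def influent():
    return make_influent()


@pytest.fixture(scope="session")
def tables():
    return AnalysisTables.default()


@pytest.fixture(scope="session")
def tiny_toy():
    return make_toy_system("tiny")


@pytest.fixture(scope="session")
def small_toy():
    return make_toy_system("small")


@pytest.fixture(scope="session")
def small_toy_run(small_toy):
    """One converged steady state of the small encapsulated toy, shared
    across tests that only need a plausible simulation output."""
    system = assemble_system(small_toy["config"], small_toy["influent"],
                             small_toy["params"], small_toy["settings"])
    result = integrate_to_steady_state(system)
    assert result.converged
    return system, result


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
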