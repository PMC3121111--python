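import pytest

from fluxtarget import solve_medication, solve_pathologic, toy_network


@pytest.fixture(scope="session")
def toy():
    """(network, config, scenario-1 ranges, scenario-2 ranges)."""
    return toy_network()


@pytest.fixture(scope="session")
def toy_pathologic(toy):
    network, config, _, _ = toy
    return solve_pathologic(network, config)


@pytest.fixture(scope="session")
def toy_medication(toy, toy_pathologic):
    network, config, ranges1, _ = toy
    return solve_medication(network, config, ranges1, reference=toy_pathologic)
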