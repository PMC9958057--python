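import pytest

from rrqspr import (
    HexSystem,
    build_graph,
    hexagonal_system,
    load_fixture,
)


@pytest.fixture
def six_cycle():
    return build_graph([(i, (i + 1) % 6) for i in range(6)])


@pytest.fixture
def path3():
    return build_graph([(1, 2), (2, 3)])


@pytest.fixture
def naphthalene():
    """Two fused hexagons: 10 vertices, 11 edges."""
    return hexagonal_system(HexSystem.chain(2))


@pytest.fixture(scope="session")
def benzenoid_properties():
    return load_fixture("benzenoid_properties")


@pytest.fixture(scope="session")
def benzenoid_ti():
    return load_fixture("benzenoid_ti")


@pytest.fixture(scope="session")
def hap():
    return load_fixture("hap_partition")
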