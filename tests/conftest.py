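import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_path():
    from netprev.catalog import packaged_fixture

    return packaged_fixture("table1.tsv")


@pytest.fixture(scope="session")
def table2_path():
    from netprev.catalog import packaged_fixture

    return packaged_fixture("table2.tsv")


@pytest.fixture(scope="session")
def table1(table1_path):
    from netprev.catalog import load_associations

    return load_associations(table1_path)


@pytest.fixture(scope="session")
def table2(table2_path):
    from netprev.catalog import load_drug_table

    return load_drug_table(table2_path)


@pytest.fixture
def toy_graph():
    """Five-node graph with a hand-enumerable module growth order."""
    g = nx.Graph()
    g.add_edges_from([("A", "C"), ("B", "C"), ("A", "D"), ("C", "E")])
    return g


@pytest.fixture(scope="session")
def planted_network():
    """One synthetic interactome with planted module, shared across tests."""
    from netprev.synthetic import GeneratorConfig, gen_interactome

    config = GeneratorConfig(rng_seed=7)
    graph, truth = gen_interactome(config)
    return graph, truth
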