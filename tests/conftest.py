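import pytest

from overrep.fixtures import (SimulationConfig, make_collection, make_dag,
                              make_mapping, make_query)


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale scenario: fast but non-trivial."""
    return SimulationConfig(seed=42, universe_size=300, n_sets=20,
                            set_size_range=(20, 40), query_size=30,
                            signal_fraction=0.5, dag_terms=30)


@pytest.fixture(scope="session")
def small_collection(small_config):
    return make_collection(small_config)


@pytest.fixture(scope="session")
def small_dag(small_config):
    return make_dag(small_config)


@pytest.fixture(scope="session")
def small_mapping(small_config):
    return make_mapping(small_config, n_loci=80)


@pytest.fixture(scope="session")
def planted_run(small_config, small_collection):
    collection, background = small_collection
    query, truth = make_query(small_config, collection, background)
    return collection, background, query, truth
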