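import pytest

import drugsynergy as ds


@pytest.fixture(scope="session")
def toy():
    """The worked 10-reaction instance: (model, catalog, objective id)."""
    return ds.toy_instance()


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_catalog(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_solution(toy):
    model, catalog, objective = toy
    return ds.solve_optimal_combination(model, catalog, objective)


@pytest.fixture(scope="session")
def bottleneck():
    return ds.bottleneck_fixture()
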