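import warnings

import pytest

from mcf import synthetic_data as syn
from mcf.api import MCFModel


@pytest.fixture(scope="session")
def planted_spec():
    return syn.SimulationSpec(seed=0)


@pytest.fixture(scope="session")
def planted_network(planted_spec):
    return syn.make_toy_model(planted_spec)


@pytest.fixture(scope="session")
def planted_cohort(planted_spec, planted_network):
    expr, labels = syn.simulate_expression(planted_network, planted_spec)
    return expr, labels


@pytest.fixture(scope="session")
def planted_model(planted_network, planted_cohort):
    expr, labels = planted_cohort
    return MCFModel(expr, labels, planted_network)


@pytest.fixture(scope="session")
def planted_results(planted_model):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return planted_model.fit()
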