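import pytest
from hypothesis import settings

import tptnp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig7():
    return tptnp.fig7_fixture()


@pytest.fixture(scope="session")
def fig7_network(fig7):
    return tptnp.build_tpt(fig7.annotation)


@pytest.fixture(scope="session")
def fig7_partition(fig7_network):
    return tptnp.detect_modules(fig7_network, resolution=1.0, seed=0)


@pytest.fixture(scope="session")
def fig7_cm(fig7, fig7_partition):
    incidence_u = tptnp.module_pathway_incidence(fig7_partition, fig7.annotation)
    return tptnp.contribution_scores(incidence_u, fig7.pathway_disease)
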