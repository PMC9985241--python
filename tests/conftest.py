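"""Shared fixtures: a seeded synthetic KEGG dataset and local servers."""
from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from keggfetch.mock import MockKEGGServer, generate_dataset
from keggfetch.rest import KEGGrest, RequestPolicy

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Sizes of the synthetic databases every test shares.  "brite" has
#: three listed-but-unavailable entries, mirroring the real Brite
#: database's permanently absent records; "module" is empty.
DATASET_SEED = 1337
DATASET_SIZES = {"compound": 60, "drug": 40, "hsa": 8, "brite": 12, "module": 0}
DATASET_UNAVAILABLE = {"brite": 3}


@pytest.fixture(scope="session")
def dataset():
    return generate_dataset(DATASET_SEED, DATASET_SIZES, DATASET_UNAVAILABLE)


@pytest.fixture
def make_server(dataset):
    """Factory for started mock servers; all are stopped at teardown."""
    started = []

    def _make(quirks=None, custom_dataset=None):
        server = MockKEGGServer(custom_dataset or dataset, quirks)
        server.start()
        started.append(server)
        return server

    yield _make
    for server in started:
        server.stop()


@pytest.fixture
def server(make_server):
    return make_server()


def client_for(server, **policy_kwargs) -> KEGGrest:
    policy_kwargs.setdefault("timeout", 5.0)
    return KEGGrest(server.base_url, RequestPolicy(**policy_kwargs))


@pytest.fixture
def client(server):
    return client_for(server)
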