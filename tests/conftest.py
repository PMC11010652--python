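from pathlib import Path

import pytest

from sigfetch.container import read_all
from sigfetch.fixtures import FixtureSpec, ServerBehavior, generate_dataset, serve


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Shared 120-read dataset; tests must not mutate its files."""
    d = tmp_path_factory.mktemp("dataset")
    return generate_dataset(
        FixtureSpec(n_reads=120, signal_length=(1500, 300), seed=42), d
    )


@pytest.fixture(scope="session")
def dataset_dir(dataset):
    return Path(dataset.container_path).parent


@pytest.fixture(scope="session")
def local_reads(dataset):
    """(header, records) decoded locally — the oracle for remote access."""
    return read_all(dataset.container_path)


@pytest.fixture
def start_server(dataset_dir):
    """Factory for instrumented range servers; all shut down at teardown."""
    handles = []

    def _start(behavior: ServerBehavior | None = None, directory=None):
        handle = serve(directory or dataset_dir, behavior)
        handles.append(handle)
        return handle

    yield _start
    for handle in handles:
        handle.shutdown()
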