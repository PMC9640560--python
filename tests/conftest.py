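import pytest
from hypothesis import settings

from tpmtscreen import datasets, default_registry

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def seq_matrix(registry):
    return datasets.load_sequence_calls(registry)


@pytest.fixture(scope="session")
def struct_matrix(registry):
    return datasets.load_structure_calls(registry)


@pytest.fixture(scope="session")
def benchmark_seq(registry):
    return datasets.load_benchmark_sequence_calls(registry)


@pytest.fixture(scope="session")
def benchmark_struct(registry):
    return datasets.load_benchmark_structure_calls(registry)


@pytest.fixture(scope="session")
def gold_entries():
    return datasets.load_benchmark_evidence()
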