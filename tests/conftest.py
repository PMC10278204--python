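import warnings

import pytest

from idptransfer.io import read_disprot_json
from idptransfer.simulate import benchmark_families, make_disprot_fixture

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def clean_families():
    return benchmark_families("clean", seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def decoy_families():
    return benchmark_families("decoy", seed=BENCHMARK_SEED)


def _fixture_dir(families, tmp_path_factory, name):
    out = tmp_path_factory.mktemp(name)
    make_disprot_fixture(families, out)
    return out


@pytest.fixture(scope="session")
def clean_fixture_dir(clean_families, tmp_path_factory):
    return _fixture_dir(clean_families, tmp_path_factory, "clean_fixture")


@pytest.fixture(scope="session")
def decoy_fixture_dir(decoy_families, tmp_path_factory):
    return _fixture_dir(decoy_families, tmp_path_factory, "decoy_fixture")


@pytest.fixture(scope="session")
def clean_entries(clean_fixture_dir):
    return read_disprot_json(clean_fixture_dir / "entries.json").entries


@pytest.fixture(scope="session")
def decoy_entries(decoy_fixture_dir):
    return read_disprot_json(decoy_fixture_dir / "entries.json").entries


@pytest.fixture(autouse=True)
def _quiet_missing_canonical_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="no canonical sequence map supplied"
        )
        yield
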