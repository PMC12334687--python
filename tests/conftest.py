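import shutil

import pytest

from mrsbids import fixtures, generate_dataset


@pytest.fixture(scope="session")
def valid_dataset(tmp_path_factory):
    """A small valid dataset (2 subjects x 1 session, svs + mrsref)."""
    root = tmp_path_factory.mktemp("valid") / "ds"
    generate_dataset(fixtures.default_fixture_spec(seed=7), root)
    return root


@pytest.fixture(scope="session")
def mutation_template(tmp_path_factory):
    """Read-only template dataset covering every mutation target."""
    root = tmp_path_factory.mktemp("template") / "ds"
    generate_dataset(fixtures.mutation_fixture_spec(seed=7), root)
    return root


@pytest.fixture
def mutable_dataset(mutation_template, tmp_path):
    """A fresh writable copy of the template, one per test."""
    dest = tmp_path / "ds"
    shutil.copytree(mutation_template, dest)
    return dest
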