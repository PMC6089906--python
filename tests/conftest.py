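from pathlib import Path

import pytest
from hypothesis import settings

from taxobench import load_taxdump

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def nodes_path() -> Path:
    return DATA / "mini_nodes.tsv"


@pytest.fixture(scope="session")
def names_path() -> Path:
    return DATA / "mini_names.tsv"


@pytest.fixture(scope="session")
def db(nodes_path, names_path):
    """The 40-node miniature taxonomy shared by the whole suite."""
    return load_taxdump(nodes_path, names_path)
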