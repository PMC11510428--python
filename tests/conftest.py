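import pytest

from azogen import generate_corpus
from azogen.data import table2


@pytest.fixture(scope="session")
def small_corpus():
    """A small mixed corpus (10% motif molecules) shared across tests."""
    return generate_corpus(300, seed=11, motif_fraction=0.1)


@pytest.fixture(scope="session")
def table2_smiles() -> list[str]:
    return list(table2()["smiles"])
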