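import pytest

from pmhcdock.fixtures import ToyComplexSpec, make_toy_complex
from pmhcdock.registry import AllotypeRegistry


@pytest.fixture(scope="session")
def toy9():
    """(complex, template) for a 9-mer toy pMHC-I fixture."""
    return make_toy_complex(ToyComplexSpec(peptide_length=9, seed=1))


@pytest.fixture(scope="session")
def toy8():
    return make_toy_complex(ToyComplexSpec(peptide_length=8, seed=1))


@pytest.fixture(scope="session")
def toy10():
    return make_toy_complex(ToyComplexSpec(peptide_length=10, seed=1))


@pytest.fixture(scope="session")
def toy_registry(toy8, toy9, toy10):
    return AllotypeRegistry([toy8[1], toy9[1], toy10[1]])
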