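import pytest

from flakit import datasets


@pytest.fixture(scope="session")
def ptrfla_loci():
    return datasets.load_ptrfla_loci()


@pytest.fixture(scope="session")
def ptrfla_pairs():
    return datasets.load_ptrfla_pairs()
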