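import pytest

from navclamp.params import VariantLibrary, default_library


@pytest.fixture(scope="session")
def library() -> VariantLibrary:
    return default_library()


@pytest.fixture(scope="session")
def wt(library):
    return library["WT"]


@pytest.fixture(scope="session")
def n1662d(library):
    return library["N1662D"]
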