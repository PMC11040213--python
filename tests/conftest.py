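import pytest

from pregepisodes.config import (
    AlgorithmParams,
    default_codelist_path,
    load_codemap,
)


@pytest.fixture(scope="session")
def params() -> AlgorithmParams:
    return AlgorithmParams()


@pytest.fixture(scope="session")
def codemap():
    return load_codemap(default_codelist_path())
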