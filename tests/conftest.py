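import pytest

from bovmt import load_haplogroup_config, load_reference


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def backbone():
    return load_haplogroup_config()
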