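import pytest

from sscc import GroupSpec, key_gen


@pytest.fixture(scope="session")
def spec():
    return GroupSpec()


@pytest.fixture(scope="session")
def keys(spec):
    # one deterministic key pair shared by the whole suite; key generation
    # itself is covered by dedicated tests
    return key_gen(spec, seed=0xC0FFEE)
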