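import pytest

from rootcea import base_case


@pytest.fixture(scope="session")
def config():
    """Packaged base-case configuration."""
    return base_case()
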