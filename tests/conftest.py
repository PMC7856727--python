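import pytest

from hkpim import load_default_criteria


@pytest.fixture(scope="session")
def criteria():
    """The packaged Hong Kong-specific criteria set (read-only)."""
    return load_default_criteria()
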