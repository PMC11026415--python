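from dataclasses import replace

import pytest

from capspec import (
    DEFAULT_ACID,
    REVISED_25C,
    REVISED_37C,
    TitrationProtocol,
)


@pytest.fixture(scope="session")
def acid():
    return DEFAULT_ACID


@pytest.fixture(scope="session")
def acid_37c():
    return replace(DEFAULT_ACID, temperature=310.15)


@pytest.fixture(scope="session")
def revised():
    return REVISED_25C


@pytest.fixture(scope="session")
def revised_37c():
    return REVISED_37C


@pytest.fixture
def protocol():
    """Factory for dosing protocols at a given pH (reference defaults)."""

    def make(ph: float, **kw) -> TitrationProtocol:
        return TitrationProtocol(target_ph=ph, **kw)

    return make
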