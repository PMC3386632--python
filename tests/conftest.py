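import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from degrinscan.simulate import generate_proteome


@pytest.fixture(scope="session")
def audited_proteome():
    """A ledger-audited fixture proteome shared across tests (n=200)."""
    return generate_proteome(n=200, seed=11)


@pytest.fixture(scope="session")
def small_proteome():
    return generate_proteome(n=50, seed=7)
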