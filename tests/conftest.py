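import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracles module

from trfscreen.energy import load_default_model
from trfscreen.simulate import SimConfig


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture()
def cfg():
    """Default stated world (documented default seed)."""
    return SimConfig()


@pytest.fixture()
def small_cfg():
    """Scaled-down world for pipeline-level tests (runtime, not statistics)."""
    return SimConfig(n_trnas=12, n_genes=600, utr_len=200)
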