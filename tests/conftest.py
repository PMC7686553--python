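import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from gliaquant.core import CortexLayout


@pytest.fixture
def small_layout() -> CortexLayout:
    """Two-band field small enough for fast rendering."""
    return CortexLayout(
        layer_widths=[("II/III", 80.0), ("V", 120.0)],
        field_size_um=(200.0, 150.0, 10.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
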