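import numpy as np
import pytest
from hypothesis import settings

from regulogic.bf_core import TruthTable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def worked_example_tt():
    """Three-minterm k=3 function: rows 000, 010, 100 map to 1
    (minimal formula ~x1 & (~x2 | ~x3))."""
    return TruthTable.from_mask(0b00010101, 3)


def sig3(x: float) -> float:
    """Round to three significant figures (Table-style formatting)."""
    return float(f"{x:.3g}")
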