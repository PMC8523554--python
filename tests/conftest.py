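import numpy as np
import pytest

from cellrheo import HierParams


@pytest.fixture
def cytoplasm() -> HierParams:
    """1-level cytoplasm ladder: E1 = 100 Pa, tau = 300 s."""
    return HierParams([100.0], viscosity=3.0e4)


@pytest.fixture
def cell2() -> HierParams:
    """2-level cell, equal stiffness."""
    return HierParams([100.0, 100.0], viscosity=3.0e4)


@pytest.fixture
def cell3() -> HierParams:
    """3-level cell, equal stiffness."""
    return HierParams([100.0, 100.0, 100.0], viscosity=3.0e4)


@pytest.fixture
def hasm() -> HierParams:
    """HASM-like 3-level cell with the measured cytoplasmic viscosity."""
    return HierParams([100.0, 100.0, 100.0], viscosity=1.41)


@pytest.fixture
def tau(cytoplasm) -> float:
    return cytoplasm.relaxation_time


def log_grid(lo: float, hi: float, n: int) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n)
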