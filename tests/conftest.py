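import numpy as np
import pytest

from switchjxn.caller import CallerParams


@pytest.fixture
def tiny_params() -> CallerParams:
    """Short-flank parameters for constructed toy junctions."""
    return CallerParams(min_flank=2)


@pytest.fixture
def oracle_params() -> CallerParams:
    """Parameters for oracle-equivalence checks on small random instances."""
    return CallerParams(min_flank=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
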