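import numpy as np
import pytest

from felas.landscape import apply_spacer_threshold, build_periodic_profile


@pytest.fixture(scope="session")
def p10_np10():
    """Thresholded sin^2 pattern, k=10, Np=10 (spacers at 0 and 5)."""
    return apply_spacer_threshold(build_periodic_profile(10, 10))


@pytest.fixture(scope="session")
def p25_np50():
    return apply_spacer_threshold(build_periodic_profile(25, 50))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
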