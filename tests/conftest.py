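import numpy as np
import pytest

from monopet.geometry import build_scanner, design_a, design_b


@pytest.fixture(scope="session")
def geom_a():
    return build_scanner(design_a())


@pytest.fixture(scope="session")
def geom_b():
    return build_scanner(design_b())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
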