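import numpy as np
import pytest

from fuskit.stimulus import build_protocol
from fuskit.synthetic import default_phantom_spec, generate_phantom


@pytest.fixture(scope="session")
def phantom64():
    """64x64 phantom with the default eight-region layout."""
    return generate_phantom(default_phantom_spec((64, 64), vessel_density=0.1), seed=11)


@pytest.fixture(scope="session")
def phantom32():
    return generate_phantom(default_phantom_spec((32, 32), vessel_density=0.1), seed=7)


@pytest.fixture(scope="session")
def paper_protocol():
    """30 s initial rest + 5 x (30 s stim + 45 s rest), 0.4 s frames."""
    with pytest.warns(UserWarning):
        return build_protocol(30, 30, 45, 5, 0.4)


@pytest.fixture(scope="session")
def short_protocol():
    """Desk-scale block design for fast cohort simulations."""
    return build_protocol(10, 5, 10, 3, 0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
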