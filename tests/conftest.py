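import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tbeam_section():
    """The study's T-shaped shuttle cross-section."""
    from shuttlesim.geometry import TBeamSection

    return TBeamSection(65.0, 11.0, 27.5, 16.0, 2.0)


@pytest.fixture
def rect34_section():
    """The 65 x 34 um silicon rectangle of matched buckling strength."""
    from shuttlesim.geometry import RectangularSection

    return RectangularSection(65.0, 34.0)
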