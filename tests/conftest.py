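import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from respispec import MotionSpec, SpectrometerConfig, simulate_acquisition

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_cfg() -> SpectrometerConfig:
    """A reduced detector (128 pixels around the laser line) for fast tests."""
    return SpectrometerConfig(wavelength_grid=np.linspace(600.0, 700.0, 128))


@pytest.fixture
def small_sim(small_cfg):
    """Factory: simulate a recording on the reduced detector."""

    def _sim(frequency=0.3291, displacement=2.0, duration=60.0, noise=None, **kwargs):
        spec = MotionSpec(frequency=frequency, displacement=displacement,
                          duration=duration, **kwargs)
        return simulate_acquisition(spec, cfg=small_cfg, noise=noise)

    return _sim
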