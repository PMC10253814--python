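import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rod_map():
    """Factory for small synthetic maps containing flat-topped rods."""
    from fibrilkit.afm import HeightMap

    def build(rods, shape=(64, 64), pixel_size=1.0, background=None):
        bg = np.zeros(shape) if background is None else np.asarray(background)
        z = bg.copy()
        for (r0, r1, c0, c1, h) in rods:
            # rod height h above the local background; overlaps take the max
            z[r0:r1, c0:c1] = np.maximum(
                z[r0:r1, c0:c1], bg[r0:r1, c0:c1] + h
            )
        return HeightMap(heights=z, pixel_size=pixel_size, source_id="test")

    return build


@pytest.fixture
def clean_trace():
    """Noise-free sigmoidal trace with known parameters."""
    from fibrilkit.kinetics import KineticTrace, boltzmann_model

    t = np.arange(0.0, 201.0, 2.0)
    y = boltzmann_model(t, 0.0, 1.0, 67.0, 79.0)
    return KineticTrace(times=t, intensities=y, condition="control", replicate=0)
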