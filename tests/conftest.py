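import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scprofiler import (
    ChannelImage,
    HelixSpec,
    render_helix,
    run_pipeline,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def helix800():
    """The canonical validation helix: a = 800 nm, b = 1/1612 nm^-1,
    pixel 32.24 nm, 40 nm PSF, no noise, ~3 periods."""
    spec = HelixSpec()
    axis, central, truth = render_helix(spec)
    return spec, axis, central, truth


@pytest.fixture(scope="session")
def helix800_result(helix800):
    _, axis, _, _ = helix800
    return run_pipeline(axis)


@pytest.fixture(scope="session")
def helix800_rotated_result(helix800):
    _, axis, _, _ = helix800
    rotated = ChannelImage(
        np.rot90(axis.pixels).copy(), axis.pixel_size_nm, "axis"
    )
    return run_pipeline(rotated)


@pytest.fixture(scope="session")
def helix650_result():
    axis, _, _ = render_helix(HelixSpec(a_nm=650.0))
    return run_pipeline(axis)
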