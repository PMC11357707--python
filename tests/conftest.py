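import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dmwasim as d
from dmwasim.verification import uniform_block

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    return d.load_default_library()


@pytest.fixture(scope="session")
def phantom_1mm():
    """Default phantom with the applicator placed, 1 mm spacing."""
    spec = d.PhantomSpec()
    pose = d.default_pose(spec)
    grid = d.place_applicator(d.build_phantom(spec, 1e-3), pose)
    return spec, pose, grid


@pytest.fixture()
def cancellous_block():
    """Homogeneous 16 mm cancellous cube, no air, no applicator."""
    return uniform_block("cancellous bone", (16, 16, 16))


def make_static_field(grid, values_final, initial=20.0, duration=210.0):
    """Two-snapshot TemperatureField: uniform initial, prescribed final."""
    values = np.stack([np.full(grid.shape, float(initial)),
                       np.asarray(values_final, float)])
    return d.TemperatureField(grid=grid, times=np.array([0.0, duration]),
                              values=values)
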