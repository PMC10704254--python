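import numpy as np
import pytest

from lscikit import SimulatorConfig, WindowSpec


@pytest.fixture(scope="session")
def small_sim_config() -> SimulatorConfig:
    """Tiny unbinned ensemble used by I/O and CLI round-trip tests."""
    return SimulatorConfig(
        fine_grid=80, correlation_radius_px=3.0, bin_factor=1, n_realizations=3, seed=7
    )


@pytest.fixture
def stack_3frames(small_sim_config):
    from lscikit.simulate import _camera_frame

    return np.stack([_camera_frame(small_sim_config, i) for i in range(3)])


@pytest.fixture
def w31() -> WindowSpec:
    return WindowSpec(side=3, p=1)


@pytest.fixture
def w73() -> WindowSpec:
    return WindowSpec(side=7, p=3)
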