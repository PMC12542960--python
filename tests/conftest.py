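import numpy as np
import pytest

from microdyn.simulate import AcquisitionConfig, TipDynamics, build_cell_model, simulate_surveillance


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionConfig:
    """Compact noiseless grid used by most geometry tests."""
    return AcquisitionConfig(
        fov_xy=100.0,
        voxel_size_xy=1.0,
        stack_depth=24.0,
        voxel_size_z=2.0,
        frame_interval_s=60.0,
        n_frames=12,
        noise_model=None,
    )


@pytest.fixture(scope="session")
def star_model():
    """Four straight unbranched arms of 20 μm."""
    return build_cell_model(n_primary=4, branch_prob=0.0, length_scale=20.0, seed=1)


@pytest.fixture(scope="session")
def sim_result(star_model, small_acq):
    return simulate_surveillance(star_model, small_acq, TipDynamics(mean_speed=2.0, speed_sd=0.3), seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
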