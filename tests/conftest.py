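import numpy as np
import pytest

from biospeckle.synthetic import (
    CameraModel,
    DecorrelationModel,
    OpticalGeometry,
    simulate_sequence,
)


@pytest.fixture(scope="session")
def geometry():
    return OpticalGeometry()


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def noiseless_camera():
    """16-bit, zero readout noise: quantization error is negligible."""
    return CameraModel(bit_depth=16, readout_noise_e=0.0, full_well_scale=50.0)


@pytest.fixture(scope="session")
def short_sequence(geometry, camera):
    """A 3-second 64x64 acquisition with moderate decorrelation."""
    return simulate_sequence(
        geometry,
        camera,
        DecorrelationModel(rho=0.95, label="control"),
        fps=15.0,
        duration_s=3.0,
        seed=42,
        shape=(64, 64),
        plant_id=1,
        age_dap=30,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
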