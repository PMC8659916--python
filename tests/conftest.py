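import numpy as np
import pytest

from holophase import (
    ReferenceWaveParams,
    make_rbc_phase,
    random_scene,
    synthesize_hologram,
)

# carrier with a deliberate sub-bin residual so integer recentring leaves
# something for the tilt search to find
STUDY_CARRIER = ReferenceWaveParams(fx=0.22 + 0.31 / 256, fy=-0.22 - 0.17 / 256)


@pytest.fixture(scope="session")
def study_scene():
    """One representative 256x256 field of biconcave cells."""
    return random_scene(7)


@pytest.fixture(scope="session")
def study_phase(study_scene):
    return make_rbc_phase(study_scene)


@pytest.fixture(scope="session")
def study_hologram(study_phase):
    return synthesize_hologram(
        study_phase, 1.0, STUDY_CARRIER, noise_sigma=0.02, seed=11, background_drift=0.05
    )


def wrapped(phase):
    return np.angle(np.exp(1j * phase))


def piston_free_rmse(a, b):
    """RMSE between two wrapped phase maps after removing the global piston."""
    diff = a - b
    piston = np.angle(np.mean(np.exp(1j * diff)))
    err = np.angle(np.exp(1j * (diff - piston)))
    return float(np.sqrt(np.mean(err**2)))
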