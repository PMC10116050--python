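"""Shared fixtures: seeded synthetic subjects, calibrations and models.

Session-scoped where construction is expensive; every fixture is fully
deterministic so the suite is reproducible run to run.
"""

import numpy as np
import pytest

from myoreach.pattern_recognition import build_training_set, train
from myoreach.processing import calibrate
from myoreach.synthetic import dmd_profile, healthy_profile, make_calibration_kit


@pytest.fixture(scope="session")
def healthy():
    return healthy_profile()


@pytest.fixture(scope="session")
def dmd():
    return dmd_profile()


@pytest.fixture(scope="session")
def healthy_kit(healthy):
    return make_calibration_kit(healthy, seed=11)


@pytest.fixture(scope="session")
def dmd_kit(dmd):
    return make_calibration_kit(dmd, seed=12)


@pytest.fixture(scope="session")
def healthy_calib(healthy_kit):
    return calibrate(healthy_kit.mvc, healthy_kit.rest)


@pytest.fixture(scope="session")
def dmd_calib(dmd_kit):
    return calibrate(dmd_kit.mvc, dmd_kit.rest)


@pytest.fixture(scope="session")
def healthy_training_set(healthy_kit):
    return build_training_set(healthy_kit.training)


@pytest.fixture(scope="session")
def healthy_model(healthy_training_set):
    X, y = healthy_training_set
    return train(X, y, seed=11)


def sine_recording(freq_hz, amplitude=1.0, duration_s=5.0, fs=1000.0):
    """Six-channel recording with the same sinusoid on every channel."""
    from myoreach.recording import EmgRecording

    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return EmgRecording(
        samples=np.tile(x, (6, 1)),
        fs=fs,
        channel_roles=("fcu", "ecu", "mid1", "mid2", "mid3", "mid4"),
    )
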