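import numpy as np
import pytest

from pelvigrf.calibration import bowing_calibration
from pelvigrf.grf_pipeline import run_pipeline
from pelvigrf.synthetic import SimConfig, simulate_trial

NOISE_FREE = dict(accel_noise=0.0, gyro_noise=0.0, gyro_bias=(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def nw_trial_clean():
    """Noise-free normal-walk trial with calibration prefix."""
    return simulate_trial(SimConfig(task="NW", seed=5, **NOISE_FREE))


@pytest.fixture(scope="session")
def nw_trial_noisy():
    """Normal walk with the default MTw-class sensing chain."""
    return simulate_trial(SimConfig(task="NW", seed=5))


@pytest.fixture(scope="session")
def standing_trial_clean():
    return simulate_trial(SimConfig(task="standing", seed=3, **NOISE_FREE))


def calibrate(trial):
    return bowing_calibration(trial.imu, trial.still_window, trial.bow_windows)


@pytest.fixture(scope="session")
def nw_estimate_clean(nw_trial_clean):
    cal = calibrate(nw_trial_clean)
    return run_pipeline(nw_trial_clean.imu, cal,
                        nw_trial_clean.config.mass_kg)


@pytest.fixture(scope="session")
def nw_estimate_noisy(nw_trial_noisy):
    cal = calibrate(nw_trial_noisy)
    return run_pipeline(nw_trial_noisy.imu, cal,
                        nw_trial_noisy.config.mass_kg)


@pytest.fixture(scope="session")
def standing_estimate_clean(standing_trial_clean):
    cal = calibrate(standing_trial_clean)
    return run_pipeline(standing_trial_clean.imu, cal,
                        standing_trial_clean.config.mass_kg)


def rms(x, axis=0):
    return np.sqrt(np.mean(np.square(x), axis=axis))
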