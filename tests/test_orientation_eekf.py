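import numpy as np
import pytest

from pelvigrf.errors import BootstrapError
from pelvigrf.orientation_eekf import (
    EekfConfig,
    EekfState,
    bootstrap_initial_heading,
    eekf_predict,
    eekf_update_inclination,
    track_orientation,
)
from pelvigrf.recordings import ImuRecording
from pelvigrf.rotations import exp_so3, rotation_angle_deg
from pelvigrf.signalproc import UniformSeries
from tests.conftest import calibrate

FS = 100.0
E3 = np.array([0.0, 0.0, 1.0])


def make_imu(accel, gyro):
    return ImuRecording(
        UniformSeries(0.0, FS, accel), UniformSeries(0.0, FS, gyro), "pelvis"
    )


def tilt_deg(r, up_body=E3):
    return np.degrees(np.arccos(np.clip((r.T @ E3) @ up_body, -1, 1)))


@pytest.fixture
def cfg():
    return EekfConfig()


@pytest.fixture
def state(cfg):
    return EekfState.initial(np.eye(3), np.zeros(3), cfg)


class TestPredict:
    def test_compensated_rate_leaves_orientation_but_grows_covariance(
        self, state, cfg
    ):
        state.b_hat = np.array([0.01, -0.02, 0.03])
        out = eekf_predict(state, state.b_hat, 0.01, cfg)
        assert np.allclose(out.r_hat, np.eye(3))
        assert np.trace(out.p) > np.trace(state.p)

    def test_quarter_turn_about_body_z(self, state, cfg):
        out = eekf_predict(state, np.array([0, 0, np.pi / 2]), 1.0, cfg)
        expected = exp_so3(np.array([0, 0, np.pi / 2]))
        assert np.allclose(out.r_hat, expected, atol=1e-9)

    def test_orthonormality_after_many_random_steps(self, state, cfg):
        rng = np.random.default_rng(0)
        s = state
        for _ in range(1000):
            s = eekf_predict(s, rng.normal(0, 0.5, 3), 0.01, cfg)
        assert np.allclose(s.r_hat @ s.r_hat.T, np.eye(3), atol=1e-9)
        assert np.allclose(s.p, s.p.T, atol=1e-12)


class TestInclinationUpdate:
    def test_aligned_gravity_gives_zero_innovation(self, state, cfg):
        out = eekf_update_inclination(state, np.array([0, 0, 9.81]), cfg)
        assert np.allclose(out.r_hat, np.eye(3), atol=1e-12)

    def test_static_tilt_error_decays(self, cfg):
        r0 = exp_so3(np.radians(5.0) * np.array([1.0, 0, 0]))
        s = EekfState.initial(r0, np.zeros(3), cfg)
        a = np.array([0, 0, 9.81])
        errs = [tilt_deg(s.r_hat)]
        for _ in range(500):  # 5 s at 100 Hz
            s = eekf_predict(s, np.zeros(3), 1 / FS, cfg)
            s = eekf_update_inclination(s, a, cfg)
            errs.append(tilt_deg(s.r_hat))
        assert errs[-1] < 0.5
        # decay is monotone up to numerical re-orthonormalisation dust
        assert np.all(np.diff(errs) < 1e-3)
        assert errs[50] < 0.1 * errs[0]

    def test_dynamic_samples_are_gated_out(self, state, cfg):
        out = eekf_update_inclination(state, np.array([0, 0, 15.0]), cfg)
        assert np.allclose(out.r_hat, state.r_hat)
        assert np.allclose(out.p, state.p)

    def test_heading_never_corrected(self, cfg):
        # start with a pure yaw error: gravity cannot see it
        from pelvigrf.rotations import yaw_matrix

        s = EekfState.initial(yaw_matrix(0.7), np.zeros(3), cfg)
        for _ in range(200):
            s = eekf_update_inclination(s, np.array([0, 0, 9.81]), cfg)
        assert np.allclose(s.r_hat, yaw_matrix(0.7), atol=1e-9)


class TestTrackOrientation:
    def test_zero_input_stays_identity(self):
        n = 200
        imu = make_imu(np.tile([0, 0, 9.81], (n, 1)), np.zeros((n, 3)))
        seq = track_orientation(imu, np.eye(3), np.zeros(3))
        assert np.allclose(seq.r[-1], np.eye(3), atol=1e-9)

    def test_yaw_is_pure_gyro_integration(self):
        # constant yaw rate, accelerometer always reads vertical gravity
        n, rate = 500, 0.4
        gyro = np.tile([0.0, 0.0, rate], (n, 1))
        accel = np.tile([0.0, 0.0, 9.81], (n, 1))
        seq = track_orientation(make_imu(accel, gyro), np.eye(3), np.zeros(3))
        expected = exp_so3(np.array([0, 0, rate * n / FS]))
        assert rotation_angle_deg(seq.r[-1] @ expected.T) < 0.1

    def test_planted_bias_recovered_on_still_data(self):
        rng = np.random.default_rng(1)
        n = 3000
        bias = np.array([0.02, -0.015, 0.0])
        accel = np.tile([0, 0, 9.81], (n, 1)) + rng.normal(0, 0.05, (n, 3))
        gyro = np.tile(bias, (n, 1)) + rng.normal(0, 0.005, (n, 3))
        cfg = EekfConfig()
        s = EekfState.initial(np.eye(3), np.zeros(3), cfg)
        for i in range(n):
            s = eekf_predict(s, gyro[i], 1 / FS, cfg)
            s = eekf_update_inclination(s, accel[i], cfg)
        # horizontal components observable through the gravity coupling
        assert np.all(np.abs(s.b_hat[:2] - bias[:2]) < 0.1 * 0.025)
        assert tilt_deg(s.r_hat) < 1.0

    def test_heading_variance_unbounded_tilt_bounded(self):
        rng = np.random.default_rng(2)
        n = 5000
        accel = np.tile([0, 0, 9.81], (n, 1)) + rng.normal(0, 0.05, (n, 3))
        gyro = rng.normal(0, 0.005, (n, 3))
        cfg = EekfConfig()
        s = EekfState.initial(np.eye(3), np.zeros(3), cfg)
        heading_var, tilt_var = [], []
        for i in range(n):
            s = eekf_predict(s, gyro[i], 1 / FS, cfg)
            s = eekf_update_inclination(s, accel[i], cfg)
            heading_var.append(s.p[2, 2])  # rotation about vertical
            tilt_var.append(s.p[0, 0] + s.p[1, 1])
        # heading grows linearly, tilt saturates
        assert heading_var[-1] > 2 * heading_var[n // 4]
        assert tilt_var[-1] < 2 * tilt_var[n // 4]


class TestBootstrap:
    def test_rotated_walk_realigned_to_x(self, nw_trial_clean):
        # world yawed 90 degrees off +X: after bootstrap the first steady
        # step's heading is +X by construction
        from pelvigrf.grf_pipeline import run_frame_chain
        from pelvigrf.gait_events import detect_initial_contacts
        from pelvigrf.synthetic import SimConfig, simulate_trial

        trial = simulate_trial(
            SimConfig(task="NW", seed=5, world_yaw_deg=90.0,
                      accel_noise=0.0, gyro_noise=0.0,
                      gyro_bias=(0.0, 0.0, 0.0))
        )
        cal = calibrate(trial)
        imu_p = trial.imu.rotated(cal.r_ps, "pelvis")
        seg = detect_initial_contacts(imu_p.accel)
        r_init = bootstrap_initial_heading(
            imu_p, segmentation=seg, bias_init=cal.gyro_bias_init
        )
        _, frames, _ = run_frame_chain(imu_p, seg, r_init,
                                       cal.gyro_bias_init)
        strongest = max(
            (f for f in frames if f.heading_xy is not None),
            key=lambda f: f.peak_speed,
        )
        # absolute heading of the anchor step in the bootstrapped frame
        ang = np.degrees(np.arctan2(strongest.heading_xy[1],
                                    strongest.heading_xy[0]))
        assert abs(ang) < 5.0

    def test_standing_only_raises(self, standing_trial_clean):
        cal = calibrate(standing_trial_clean)
        imu_p = standing_trial_clean.imu.rotated(cal.r_ps, "pelvis")
        with pytest.raises(BootstrapError):
            bootstrap_initial_heading(imu_p, bias_init=cal.gyro_bias_init)
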