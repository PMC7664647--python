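"""Error-state extended Kalman filter for pelvis orientation tracking.

The filter integrates the bias-corrected gyroscope to propagate a rotation
estimate R (mapping pelvis-frame vectors into the current step frame) and
tracks two small error states: the orientation error theta (right-multiplied,
body frame) and the gyroscope bias error.  The accelerometer corrects the
inclination only — during quasi-static motion the measured specific-force
direction is "up" in the body frame, and its discrepancy with the predicted
vertical observes the two tilt components of theta.  Rotation about the
vertical (heading) lies in the null space of that measurement, so heading is
gyro-integrated only and its uncertainty grows without bound; the per-step
frame construction downstream absorbs it.

Error convention: R_true = R_hat (I - skew(theta)), so the correction is the
right-multiplied small-angle factor, followed by re-orthonormalisation and
an error-state reset (theta -> 0).

Continuous error dynamics (first order):
    d theta / dt = -omega x theta + b_eps + n_gyro
    d b_eps / dt = n_walk
with omega the bias-corrected rate, b_eps the bias error (true minus
estimated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BootstrapError, InvalidParameterError
from .recordings import ImuRecording
from .rotations import E3, exp_so3, orthonormalize, skew, tilt_alignment

__all__ = [
    "EekfConfig",
    "EekfState",
    "RotationSequence",
    "eekf_predict",
    "eekf_update_inclination",
    "track_orientation",
    "bootstrap_initial_heading",
]

GRAVITY = 9.81  # m/s^2


@dataclass
class EekfConfig:
    """Noise settings for an MTw-class IMU; all exposed in the run config.

    gyro_noise_density : rad/s/sqrt(Hz), white rate noise.
    bias_random_walk : rad/s^2/sqrt(Hz), bias drift driving noise.
    accel_meas_noise : m/s^2, accelerometer noise used to weight the
        gravity-direction measurement.
    dynamic_rejection_gate : m/s^2, |  ||a|| - g | above which the
        inclination update is skipped (gravity no longer dominates).
    """

    gyro_noise_density: float = 5e-4
    bias_random_walk: float = 1e-4
    accel_meas_noise: float = 0.5
    dynamic_rejection_gate: float = 2.0
    p0_orientation: float = 1e-2  # rad^2, per tilt/heading axis
    p0_bias: float = 1e-4  # (rad/s)^2 per axis
    gravity: float = GRAVITY

    def __post_init__(self):
        for name in ("gyro_noise_density", "bias_random_walk",
                     "accel_meas_noise", "p0_orientation", "p0_bias",
                     "gravity"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.dynamic_rejection_gate < 0:
            raise InvalidParameterError("dynamic_rejection_gate must be >= 0")

    def initial_covariance(self) -> np.ndarray:
        return np.diag([self.p0_orientation] * 3 + [self.p0_bias] * 3)


@dataclass
class EekfState:
    """Filter state: orientation estimate, bias estimate, error covariance."""

    r_hat: np.ndarray
    b_hat: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.r_hat = np.asarray(self.r_hat, dtype=float)
        self.b_hat = np.asarray(self.b_hat, dtype=float)
        self.p = np.asarray(self.p, dtype=float)

    @classmethod
    def initial(cls, r_init: np.ndarray, bias_init: np.ndarray,
                cfg: EekfConfig) -> "EekfState":
        return cls(r_hat=np.array(r_init, dtype=float),
                   b_hat=np.array(bias_init, dtype=float),
                   p=cfg.initial_covariance())


@dataclass
class RotationSequence:
    """Per-sample orientation estimates with covariance trace, per trial."""

    t0: float
    fs: float
    r: np.ndarray  # (n, 3, 3)
    p_trace: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.r.shape[0]


def eekf_predict(state: EekfState, gyro_sample: np.ndarray, dt: float,
                 cfg: EekfConfig) -> EekfState:
    """Strapdown propagation: integrate the bias-corrected rate over dt."""
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    w = np.asarray(gyro_sample, dtype=float) - state.b_hat
    r = state.r_hat @ exp_so3(w * dt)

    phi = np.eye(6)
    phi[:3, :3] += -skew(w) * dt
    phi[:3, 3:] = np.eye(3) * dt
    q = np.zeros((6, 6))
    q[:3, :3] = (cfg.gyro_noise_density ** 2 * dt) * np.eye(3)
    q[3:, 3:] = (cfg.bias_random_walk ** 2 * dt) * np.eye(3)
    p = phi @ state.p @ phi.T + q
    return EekfState(r_hat=r, b_hat=state.b_hat.copy(), p=0.5 * (p + p.T))


def eekf_update_inclination(state: EekfState, accel_sample: np.ndarray,
                            cfg: EekfConfig) -> EekfState:
    """Tilt correction from the measured specific-force direction.

    Skipped (state passes through) when the acceleration magnitude deviates
    from g by more than the rejection gate: the accelerometer then measures
    dynamics, not gravity.
    """
    a = np.asarray(accel_sample, dtype=float)
    norm = float(np.linalg.norm(a))
    if norm < 1e-9 or abs(norm - cfg.gravity) > cfg.dynamic_rejection_gate:
        return state
    a_hat = a / norm
    v_hat = state.r_hat.T @ E3  # predicted body-frame "up"
    z = a_hat - v_hat

    h = np.zeros((3, 6))
    h[:, :3] = -skew(v_hat)
    r_meas = (cfg.accel_meas_noise / cfg.gravity) ** 2 * np.eye(3)
    s = h @ state.p @ h.T + r_meas
    k = state.p @ h.T @ np.linalg.solve(s, np.eye(3))
    dx = k @ z
    theta, db = dx[:3], dx[3:]

    r = orthonormalize(state.r_hat @ (np.eye(3) - skew(theta)))
    b = state.b_hat + db
    ikh = np.eye(6) - k @ h
    p = ikh @ state.p @ ikh.T + k @ r_meas @ k.T
    return EekfState(r_hat=r, b_hat=b, p=0.5 * (p + p.T))


def track_orientation(imu_p: ImuRecording, r_init: np.ndarray,
                      bias_init: np.ndarray, cfg: EekfConfig | None = None
                      ) -> RotationSequence:
    """Run the filter over a calibrated recording, one predict + update per
    sample; returns the per-sample orientation estimates."""
    cfg = cfg or EekfConfig()
    if imu_p.frame != "pelvis":
        raise InvalidParameterError("track_orientation expects pelvis-frame data")
    state = EekfState.initial(r_init, bias_init, cfg)
    dt = 1.0 / imu_p.fs
    n = imu_p.n
    rs = np.empty((n, 3, 3))
    tr = np.empty(n)
    gyro = imu_p.gyro.values
    accel = imu_p.accel.values
    for i in range(n):
        state = eekf_predict(state, gyro[i], dt, cfg)
        state = eekf_update_inclination(state, accel[i], cfg)
        rs[i] = state.r_hat
        tr[i] = np.trace(state.p)
    return RotationSequence(t0=imu_p.accel.t0, fs=imu_p.fs, r=rs, p_trace=tr)


def initial_tilt_from_accel(imu_p: ImuRecording, window_s: float = 0.5
                            ) -> np.ndarray:
    """Arbitrary-heading initial orientation: align the early mean specific
    force with the vertical (zero rotation about the vertical)."""
    n = max(1, min(imu_p.n, int(window_s * imu_p.fs)))
    mean_a = imu_p.accel.values[:n].mean(axis=0)
    return tilt_alignment(mean_a)


def bootstrap_initial_heading(imu_p: ImuRecording, cfg=None,
                              n_boot_steps: int = 3, segmentation=None,
                              bias_init=None) -> np.ndarray:
    """Estimate the initial orientation so the first step heads along +X.

    The tracking + per-step frame chain is run once over the first
    ``n_boot_steps`` steps with an arbitrary initial heading; the resulting
    first-step heading then defines the yaw correction applied to the
    initial orientation.
    """
    from .gait_events import detect_initial_contacts
    from .grf_pipeline import run_frame_chain
    from .step_frames import frame_update_rotation

    cfg = cfg or EekfConfig()
    if segmentation is None:
        segmentation = detect_initial_contacts(imu_p.accel)
    if segmentation.n_steps < n_boot_steps:
        raise BootstrapError(
            f"need at least {n_boot_steps} steps to bootstrap the heading, "
            f"found {segmentation.n_steps}"
        )
    if bias_init is None:
        bias_init = np.zeros(3)
    r0 = initial_tilt_from_accel(imu_p)
    t_stop = segmentation.ic_times[n_boot_steps]
    boot = imu_p.slice_time(imu_p.accel.t0, float(t_stop))
    boot_seg = replace_segmentation(segmentation, n_boot_steps)
    _, frames, _ = run_frame_chain(boot, boot_seg, r0, bias_init, cfg)

    # anchor the heading on the most vigorous boot step (the first detected
    # step often straddles gait initiation and its heading is unreliable)
    best, cum_before_best = None, np.eye(3)
    cum = np.eye(3)
    for f in frames:
        if f.heading_xy is not None and (
            best is None or f.peak_speed > best.peak_speed
        ):
            best, cum_before_best = f, cum.copy()
        cum = f.r_update @ cum
    if best is None:
        raise BootstrapError("no bootstrap step produced a usable heading")
    # express that step's heading in the arbitrary initial frame
    h3 = cum_before_best.T @ np.array([best.heading_xy[0],
                                       best.heading_xy[1], 0.0])
    h = h3[:2] / np.linalg.norm(h3[:2])
    return frame_update_rotation(h) @ r0


def replace_segmentation(segmentation, n_steps: int):
    """First ``n_steps`` steps of a segmentation (helper for bootstrap)."""
    from .gait_events import StepSegmentation

    return StepSegmentation(
        ic_times=segmentation.ic_times[: n_steps + 1],
        offset_applied=segmentation.offset_applied,
    )
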