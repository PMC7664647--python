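"""Synthetic over-ground gait trials with exact ground truth.

The simulator is a kinematic prescription, not a dynamic simulation: a CoM
trajectory is written down in closed form and every measured stream (IMU,
per-foot forces, pelvis markers) is derived from it, so the model assumption
the estimator rests on — total GRF = mass x CoM specific force while only
the feet touch the ground — holds exactly and the simulator truth is a
legitimate oracle for both pipelines.

A trial follows the measurement protocol: quiet standing, three forward
trunk bows (the calibration movement), a short stance, the walking task,
and a final stance.  Tasks: NW (straight 5 m), LW (3 m, 90 deg right turn,
2 m), WT (5 m, 180 deg turn, back), WT2 (out-back-out), SlW (slalom), and
"standing" (no gait).

Gait signature (inverted-pendulum-like): the CoM oscillates vertically at
the step frequency, laterally at the stride frequency (half the step rate),
and fore-aft at the step frequency.  True initial contacts sit at the
lateral-oscillation zero crossings (the CoM starts moving toward the new
stance side); the vertical-acceleration peak of each step is placed a fixed
loading-response lag (default 0.08 s) after the contact, which is the lag
the detector's uniform offset corrects for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .orientation_eekf import GRAVITY
from .recordings import FootForceRecording, ImuRecording, MarkerRecording
from .rotations import yaw_matrix
from .signalproc import UniformSeries
from .step_frames import frame_update_rotation

__all__ = ["SimConfig", "TruthData", "SyntheticTrial", "simulate_trial",
           "imu_remount", "truth_grf_in_ic_frames"]

TASKS = ("NW", "LW", "WT", "WT2", "SlW", "standing")

# fixed marker offsets in the pelvis frame (metres); centroid is exactly zero
MARKER_OFFSETS = {
    "RASI": np.array([0.12, -0.12, 0.02]),
    "LASI": np.array([0.12, 0.12, 0.02]),
    "RPSI": np.array([-0.12, -0.07, -0.02]),
    "LPSI": np.array([-0.12, 0.07, -0.02]),
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic trial.

    Defaults describe a healthy adult at preferred speed: 74.3 kg,
    1.2 m/s, 1.8 steps/s, centimetre-scale CoM oscillations, and an
    MTw-class sensing chain (accel sigma 0.05 m/s^2, gyro sigma
    0.005 rad/s, gyro bias of order 0.01 rad/s) sampled at 100 Hz.
    """

    task: str = "NW"
    mass_kg: float = 74.3
    walking_speed: float = 1.2  # m/s
    step_freq: float = 1.8  # initial contacts per second
    vertical_osc_amp: float = 0.018  # m, at step frequency
    lateral_osc_amp: float = 0.035  # m, at stride frequency
    foreaft_osc_amp: float = 0.012  # m, fundamental at step frequency
    ic_lag_s: float = 0.08  # vertical-acc peak lag behind true IC
    double_support_fraction: float = 0.2  # of one step interval
    fs: float = 100.0
    seed: int = 0
    # sensing chain
    accel_noise: float = 0.05  # m/s^2, white, per axis
    gyro_noise: float = 0.005  # rad/s, white, per axis
    gyro_bias: tuple = (0.008, -0.012, 0.01)  # rad/s, constant, sensor frame
    mounting_yaw_deg: float = 0.0  # sensor mounting yaw about pelvis Z
    # protocol timing
    include_calibration: bool = True
    still_s: float = 3.0
    bow_s: float = 6.0  # three bows of bow_s/3 each
    bow_angle_deg: float = 30.0
    pre_walk_still_s: float = 2.0
    post_walk_still_s: float = 2.0
    standing_duration_s: float = 10.0  # task length for task="standing"
    speed_ramp_s: float = 0.6
    # pelvis sway during gait
    pitch_sway_deg: float = 2.0
    roll_sway_deg: float = 2.0
    # geometry
    turn_arc_m: float = 0.8
    slalom_amp_deg: float = 30.0
    slalom_period_m: float = 4.0
    world_yaw_deg: float = 0.0
    com_height_m: float = 1.0
    gravity: float = GRAVITY

    def __post_init__(self):
        if self.task not in TASKS:
            raise InvalidParameterError(f"unknown task {self.task!r}")
        if self.fs <= 20:
            raise InvalidParameterError("fs must exceed 20 Hz")
        for name in ("vertical_osc_amp", "lateral_osc_amp", "foreaft_osc_amp",
                     "accel_noise", "gyro_noise"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass
class TruthData:
    """Noise-free ground truth, in the fixed global frame."""

    com_pos: UniformSeries
    com_vel: UniformSeries
    com_acc: UniformSeries
    grf_total: UniformSeries  # N
    ic_times: np.ndarray
    ic_sides: list[str]
    step_headings_xy: np.ndarray  # (n_steps, 2), unit vectors, global frame
    r_gp: np.ndarray  # (n, 3, 3), pelvis->global


@dataclass
class SyntheticTrial:
    truth: TruthData
    imu: ImuRecording  # sensor frame
    forces: FootForceRecording
    markers: MarkerRecording
    config: SimConfig
    still_window: tuple[float, float]
    bow_windows: list[tuple[float, float]] = field(default_factory=list)
    task_window: tuple[float, float] = (0.0, 0.0)
    r_sp: np.ndarray = field(default_factory=lambda: np.eye(3))  # v_s = r_sp v_p


def _heading_profile(cfg: SimConfig):
    """Return (total path length, chi(s) in radians) for the walking task."""
    turn = cfg.turn_arc_m
    if cfg.task == "NW":
        pts = [(0.0, 0.0), (5.0, 0.0)]
    elif cfg.task == "LW":
        pts = [(0.0, 0.0), (3.0, 0.0), (3.0 + turn, -90.0),
               (5.0 + turn, -90.0)]
    elif cfg.task == "WT":
        pts = [(0.0, 0.0), (5.0, 0.0), (5.0 + turn, 180.0),
               (10.0 + turn, 180.0)]
    elif cfg.task == "WT2":
        pts = [(0.0, 0.0), (5.0, 0.0), (5.0 + turn, 180.0),
               (10.0 + turn, 180.0), (10.0 + 2 * turn, 360.0),
               (15.0 + 2 * turn, 360.0)]
    elif cfg.task == "SlW":
        length = 6.0
        amp = np.radians(cfg.slalom_amp_deg)

        def chi(s):
            return amp * np.sin(2.0 * np.pi * np.asarray(s) / cfg.slalom_period_m)

        return length, chi
    else:  # standing
        return 0.0, lambda s: np.zeros_like(np.asarray(s, dtype=float))
    s_pts = np.array([p[0] for p in pts])
    chi_pts = np.radians([p[1] for p in pts])

    def chi(s):
        return np.interp(np.asarray(s, dtype=float), s_pts, chi_pts)

    return float(s_pts[-1]), chi


def _speed_profile(t_w: np.ndarray, dur: float, cfg: SimConfig) -> np.ndarray:
    """Cosine-ramped speed factor in [0, 1] over the walking window."""
    ramp = min(cfg.speed_ramp_s, dur / 2.0)
    r = np.ones_like(t_w)
    up = t_w < ramp
    r[up] = 0.5 * (1.0 - np.cos(np.pi * t_w[up] / ramp))
    down = t_w > dur - ramp
    r[down] = 0.5 * (1.0 - np.cos(np.pi * (dur - t_w[down]) / ramp))
    r[(t_w < 0) | (t_w > dur)] = 0.0
    return r


def _ypr_matrices(yaw, pitch, roll):
    """Pelvis->global rotations from intrinsic Z(yaw)-Y(pitch)-X(roll)."""
    cy, sy = np.cos(yaw), np.sin(yaw)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    n = yaw.shape[0]
    r = np.empty((n, 3, 3))
    r[:, 0, 0] = cy * cp
    r[:, 0, 1] = cy * sp * sr - sy * cr
    r[:, 0, 2] = cy * sp * cr + sy * sr
    r[:, 1, 0] = sy * cp
    r[:, 1, 1] = sy * sp * sr + cy * cr
    r[:, 1, 2] = sy * sp * cr - cy * sr
    r[:, 2, 0] = -sp
    r[:, 2, 1] = cp * sr
    r[:, 2, 2] = cp * cr
    return r


def _angular_rates_body(r_gp: np.ndarray, dt: float) -> np.ndarray:
    """Body-frame angular velocity from a smooth rotation sequence."""
    dr = np.gradient(r_gp, dt, axis=0)
    w_mat = np.einsum("nji,njk->nik", r_gp, dr)  # R^T dR
    w_mat = 0.5 * (w_mat - np.transpose(w_mat, (0, 2, 1)))
    return np.stack(
        [w_mat[:, 2, 1], w_mat[:, 0, 2], w_mat[:, 1, 0]], axis=1
    )


def simulate_trial(cfg: SimConfig | None = None) -> SyntheticTrial:
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    fs, dt, g = cfg.fs, 1.0 / cfg.fs, cfg.gravity
    world_yaw = np.radians(cfg.world_yaw_deg)

    # ---- timeline -------------------------------------------------------
    length, chi_of_s = _heading_profile(cfg)
    if cfg.task == "standing":
        walk_dur = cfg.standing_duration_s
    else:
        walk_dur = length / cfg.walking_speed + cfg.speed_ramp_s
    if cfg.include_calibration:
        t_bow0 = cfg.still_s
        t_walk0 = cfg.still_s + cfg.bow_s + cfg.pre_walk_still_s
        still_window = (0.25, cfg.still_s - 0.25)
        lobe = cfg.bow_s / 3.0
        bow_windows = [(t_bow0 + i * lobe, t_bow0 + (i + 1) * lobe)
                       for i in range(3)]
    else:
        t_bow0 = 0.0
        t_walk0 = 0.0
        still_window = (0.0, 0.0)
        bow_windows = []
    total = t_walk0 + walk_dur + cfg.post_walk_still_s
    n = int(round(total * fs)) + 1
    t = np.arange(n) * dt
    t_w = t - t_walk0  # walking-local time
    in_walk = (t_w >= 0) & (t_w <= walk_dur)

    # ---- CoM trajectory -------------------------------------------------
    pos = np.zeros((n, 3))
    pos[:, 2] = cfg.com_height_m
    yaw = np.full(n, world_yaw)
    pitch = np.zeros(n)
    roll = np.zeros(n)
    ic_times = np.array([])
    ic_sides: list[str] = []

    if cfg.task != "standing":
        r_fac = _speed_profile(np.clip(t_w, 0.0, walk_dur), walk_dur, cfg)
        r_fac[~in_walk] = 0.0
        speed = cfg.walking_speed * r_fac
        s = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * dt)])
        chi = chi_of_s(s) + world_yaw
        # path position by integrating the tangent
        vx, vy = speed * np.cos(chi), speed * np.sin(chi)
        px = np.concatenate([[0.0], np.cumsum(0.5 * (vx[1:] + vx[:-1]) * dt)])
        py = np.concatenate([[0.0], np.cumsum(0.5 * (vy[1:] + vy[:-1]) * dt)])

        f_step = cfg.step_freq
        phase = np.clip(t_w, 0.0, walk_dur)
        lat = cfg.lateral_osc_amp * r_fac * np.sin(np.pi * f_step * phase)
        vert = -cfg.vertical_osc_amp * r_fac * np.cos(
            2.0 * np.pi * f_step * (phase - cfg.ic_lag_s)
        ) + cfg.vertical_osc_amp * r_fac  # zero-based at walk edges
        # fore-aft fluctuation with a second harmonic: the forward-velocity
        # peak (push-off) is sharp, the trough shallow, and the peak sits at
        # the CoM's lowest point just after contact (pendular energy exchange)
        theta = 2.0 * np.pi * f_step * (phase - cfg.ic_lag_s)
        fore = cfg.foreaft_osc_amp * r_fac * (
            np.sin(theta) + 0.25 * np.sin(2.0 * theta)
        )
        tangent = np.stack([np.cos(chi), np.sin(chi)], axis=1)
        normal = np.stack([-np.sin(chi), np.cos(chi)], axis=1)
        pos[:, 0] = px + fore * tangent[:, 0] + lat * normal[:, 0]
        pos[:, 1] = py + fore * tangent[:, 1] + lat * normal[:, 1]
        pos[:, 2] = cfg.com_height_m + vert

        yaw = chi.copy()
        pitch = np.radians(cfg.pitch_sway_deg) * r_fac * np.sin(
            2.0 * np.pi * f_step * phase
        )
        roll = np.radians(cfg.roll_sway_deg) * r_fac * np.sin(
            np.pi * f_step * phase
        )

        # true initial contacts: lateral zero crossings at full stride
        n_ic = int(np.floor(walk_dur * f_step)) + 1
        cand = t_walk0 + np.arange(n_ic) / f_step
        ok = []
        for tc in cand:
            i = int(round((tc - t[0]) / dt))
            if 0 <= i < n and r_fac[i] >= 0.5:
                ok.append(tc)
        ic_times = np.asarray(ok)
        # upward lateral crossing (CoM starts moving left) -> left foot strike
        ic_sides = [
            "L" if (round((tc - t_walk0) * f_step)) % 2 == 0 else "R"
            for tc in ic_times
        ]

    # bowing: pure pelvis pitch, CoM held fixed
    if cfg.include_calibration:
        in_bow = (t >= t_bow0) & (t < t_bow0 + cfg.bow_s)
        tau = (t[in_bow] - t_bow0) / cfg.bow_s
        pitch[in_bow] = np.radians(cfg.bow_angle_deg) * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * 3.0 * tau)
        )

    r_gp = _ypr_matrices(yaw, pitch, roll)

    # ---- truth kinematics & forces --------------------------------------
    vel = np.gradient(pos, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    f_g = acc + np.array([0.0, 0.0, g])  # specific force, global frame
    grf_total = cfg.mass_kg * f_g

    # ---- per-foot split --------------------------------------------------
    w_left = _stance_weights(t, ic_times, ic_sides, cfg, t_walk0 + walk_dur)
    left = grf_total * w_left[:, None]
    right = grf_total * (1.0 - w_left)[:, None]
    # the measured total is defined as the per-foot sum so the split is
    # exact by construction (Newton's identity holds to rounding)
    grf_total = left + right

    # ---- measured streams ------------------------------------------------
    r_sp = yaw_matrix(np.radians(cfg.mounting_yaw_deg))
    f_p = np.einsum("nji,nj->ni", r_gp, f_g)  # R_gp^T f_g
    accel_s = f_p @ r_sp.T
    omega_p = _angular_rates_body(r_gp, dt)
    gyro_s = omega_p @ r_sp.T + np.asarray(cfg.gyro_bias, dtype=float)
    if cfg.accel_noise > 0:
        accel_s = accel_s + rng.normal(0.0, cfg.accel_noise, accel_s.shape)
    if cfg.gyro_noise > 0:
        gyro_s = gyro_s + rng.normal(0.0, cfg.gyro_noise, gyro_s.shape)

    markers = {
        name: UniformSeries(0.0, fs, pos + np.einsum("nij,j->ni", r_gp, off))
        for name, off in MARKER_OFFSETS.items()
    }

    # ---- true per-step headings -----------------------------------------
    headings = []
    for a, b in zip(ic_times[:-1], ic_times[1:]):
        i = int(round(((a + b) / 2.0 - t[0]) / dt))
        h = np.array([np.cos(yaw[i]), np.sin(yaw[i])])
        headings.append(h / np.linalg.norm(h))
    headings = np.asarray(headings) if headings else np.empty((0, 2))

    truth = TruthData(
        com_pos=UniformSeries(0.0, fs, pos),
        com_vel=UniformSeries(0.0, fs, vel),
        com_acc=UniformSeries(0.0, fs, acc),
        grf_total=UniformSeries(0.0, fs, grf_total),
        ic_times=ic_times,
        ic_sides=ic_sides,
        step_headings_xy=headings,
        r_gp=r_gp,
    )
    return SyntheticTrial(
        truth=truth,
        imu=ImuRecording(
            accel=UniformSeries(0.0, fs, accel_s),
            gyro=UniformSeries(0.0, fs, gyro_s),
            frame="sensor",
        ),
        forces=FootForceRecording(
            left=UniformSeries(0.0, fs, left),
            right=UniformSeries(0.0, fs, right),
        ),
        markers=MarkerRecording(markers=markers),
        config=cfg,
        still_window=still_window,
        bow_windows=bow_windows,
        task_window=(t_walk0, t_walk0 + walk_dur),
        r_sp=r_sp,
    )


def _stance_weights(t, ic_times, ic_sides, cfg: SimConfig, walk_end: float
                    ) -> np.ndarray:
    """Left-foot share of the total force: sinusoidal double-support ramps,
    exact single support in between, 50/50 while standing."""
    n = t.size
    w = np.full(n, 0.5)
    if len(ic_times) == 0:
        return w
    dt = t[1] - t[0]
    t_ds = cfg.double_support_fraction / cfg.step_freq
    current = 0.5

    def ramp_to(i0, target, start_value):
        n_ds = max(1, int(round(t_ds / dt)))
        for j in range(n_ds):
            i = i0 + j
            if i >= n:
                return
            frac = np.sin(0.5 * np.pi * (j + 1) / n_ds) ** 2
            w[i] = start_value + (target - start_value) * frac

    events = list(zip(ic_times, ic_sides)) + [(walk_end, "stand")]
    for (tc, side), (tn, _) in zip(events[:-1], events[1:]):
        i0 = int(round((tc - t[0]) / dt))
        i1 = min(n, int(round((tn - t[0]) / dt)))
        target = 1.0 if side == "L" else 0.0
        w[i0:i1] = target
        ramp_to(i0, target, current)
        current = target
    # back to double stance after gait termination
    i_end = int(round((walk_end - t[0]) / dt))
    if i_end < n:
        w[i_end:] = 0.5
        ramp_to(i_end, 0.5, current)
    return w


def imu_remount(trial: SyntheticTrial, mounting_rotation: np.ndarray
                ) -> SyntheticTrial:
    """Re-express the IMU streams under a different sensor mounting.

    ``mounting_rotation`` is the new sensor-from-pelvis rotation r_sp'
    (v_s' = r_sp' @ v_p); the measured streams are rotated by
    r_sp' @ r_sp^T, truth is untouched.
    """
    r_new = np.asarray(mounting_rotation, dtype=float)
    delta = r_new @ trial.r_sp.T
    return replace(
        trial,
        imu=trial.imu.rotated(delta, "sensor"),
        r_sp=r_new,
    )


def truth_grf_in_ic_frames(trial: SyntheticTrial, pbw: bool = False
                           ) -> UniformSeries:
    """Ground-truth total GRF expressed in per-step body-centric frames
    built from the *true* step headings (first step aligned to +X, exactly
    as the estimation pipelines bootstrap theirs)."""
    truth = trial.truth
    grf = truth.grf_total
    out = grf.values.copy()
    ic = truth.ic_times
    if ic.size >= 2:
        h0 = truth.step_headings_xy[0]
        cum = frame_update_rotation(h0 / np.linalg.norm(h0))
        bounds = [grf.index_at(tt) for tt in ic]
        out[: bounds[0]] = grf.values[: bounds[0]] @ cum.T
        for k, (i0, i1) in enumerate(zip(bounds[:-1], bounds[1:])):
            h = truth.step_headings_xy[k]
            h_prev = cum[:2, :2] @ h  # heading in frame ic(k-1)
            r_upd = frame_update_rotation(h_prev / np.linalg.norm(h_prev))
            cum = r_upd @ cum
            out[i0:i1] = grf.values[i0:i1] @ cum.T
        out[bounds[-1]:] = grf.values[bounds[-1]:] @ cum.T
    if pbw:
        out = 100.0 * out / (trial.config.mass_kg * trial.config.gravity)
    return grf.with_values(out)
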