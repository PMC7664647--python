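"""End-to-end 3D ground reaction force estimation from a pelvis IMU.

Chain: sensor-to-pelvis rotation -> initial-contact detection -> heading
bootstrap -> orientation tracking + per-step frame updates -> Newton's
second law (force = mass x specific force of the CoM) -> impact-peak
removal around initial contacts -> axis-specific zero-phase filtering ->
body-weight normalisation.

The force is expressed per step in the body-centric initial-contact frame:
X forward along the step heading, Z vertical.  At rest the estimate reads
(0, 0, 100) %BW — gravity support with no shear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationResult
from .errors import BootstrapError, InvalidParameterError, PipelineStageError
from .gait_events import StepSegmentation, detect_initial_contacts
from .orientation_eekf import (
    GRAVITY,
    EekfConfig,
    RotationSequence,
    bootstrap_initial_heading,
    initial_tilt_from_accel,
    track_orientation,
)
from .recordings import ImuRecording
from .signalproc import UniformSeries, butter_zero_phase, savgol_smooth
from .step_frames import (
    DEFAULT_MIN_HEADING_SPEED,
    DEFAULT_REL_SPEED_FRAC,
    StepFrame,
    collect_step_headings,
    frame_update_rotation,
    transform_to_previous_frame,
)

__all__ = [
    "GrfConfig",
    "GrfEstimate",
    "transform_to_current_frame",
    "compute_raw_grf",
    "remove_impact_peaks",
    "filter_grf_axes",
    "run_frame_chain",
    "run_pipeline",
]


@dataclass
class GrfConfig:
    """Every tunable of the force pipeline, with field defaults.

    Filter bands follow the axis-specific design: X band-passed 0.1-5 Hz,
    Y band-passed 0.1-3 Hz, Z low-passed 10 Hz, all order-2 zero-phase
    Butterworth.
    """

    ic_min_prominence: float = 0.2  # m/s^2
    ic_lp_cutoff_hz: float = 2.0
    ic_offset_s: float = 0.08
    ic_min_interval_s: float = 0.25
    n_boot_steps: int = 3
    peak_half_window_s: float = 0.10
    peak_savgol_window: int = 11
    band_x_hz: tuple[float, float] = (0.1, 5.0)
    band_y_hz: tuple[float, float] = (0.1, 3.0)
    lowpass_z_hz: float = 10.0
    heading_min_speed: float = DEFAULT_MIN_HEADING_SPEED  # m/s
    heading_rel_speed_frac: float = DEFAULT_REL_SPEED_FRAC
    gravity: float = GRAVITY
    eekf: EekfConfig = field(default_factory=EekfConfig)


@dataclass
class GrfEstimate:
    """Estimated 3D GRF with full per-step provenance."""

    grf_n: UniformSeries
    grf_pbw: UniformSeries
    segmentation: StepSegmentation
    frames: list[StepFrame]
    mass: float
    rotation_seq: RotationSequence | None = None


def transform_to_current_frame(
    acc_ic_prev: UniformSeries, r_update: np.ndarray
) -> UniformSeries:
    """Left-multiply every sample by the step's frame-update rotation."""
    return acc_ic_prev.with_values(acc_ic_prev.values @ np.asarray(r_update).T)


def compute_raw_grf(acc_ic: UniformSeries, mass: float) -> UniformSeries:
    """Newton's second law on specific force: F = mass * y_A.

    Specific force already contains the gravity reaction (it reads +g
    upward at rest), so no weight term is added.
    """
    if mass <= 0:
        raise InvalidParameterError("mass must be > 0")
    return acc_ic.with_values(mass * acc_ic.values)


def remove_impact_peaks(
    grf: UniformSeries,
    ic_times,
    half_window_s: float = 0.10,
    savgol_window: int = 11,
    blend_samples: int = 3,
) -> UniformSeries:
    """Adaptive removal of impact transients around each initial contact.

    Within +-``half_window_s`` of each contact, per axis: the extremal
    excursion (the sample deviating most from the window's order-3
    Savitzky-Golay fit, i.e. the impact maximum/minimum) is located, excised
    by linear interpolation across its immediate neighbourhood, and the
    window is then smoothed with the order-3 Savitzky-Golay filter.  The
    replacement is blended linearly over a few samples at the window edges;
    samples outside every window are returned bit-identical.
    """
    ic = np.asarray(ic_times, dtype=float)
    if ic.size == 0:
        return grf
    half = int(round(half_window_s * grf.fs))
    out = grf.values.copy()
    for t_ic in ic:
        c = grf.index_at(t_ic)
        lo, hi = max(0, c - half), min(grf.n, c + half + 1)
        seg_len = hi - lo
        if seg_len < savgol_window:
            continue
        seg = grf.values[lo:hi]
        seg2d = seg if seg.ndim == 2 else seg[:, None]
        cleaned = seg2d.copy()
        base = savgol_smooth(
            UniformSeries(0.0, grf.fs, seg2d), savgol_window, 3
        ).values
        resid = seg2d - base
        for ax in range(seg2d.shape[1]):
            e = int(np.argmax(np.abs(resid[:, ax])))
            a = max(0, e - 2)
            b = min(seg_len - 1, e + 2)
            cleaned[a:b + 1, ax] = np.interp(
                np.arange(a, b + 1), [a - 1 if a > 0 else a,
                                      b + 1 if b < seg_len - 1 else b],
                [seg2d[max(a - 1, 0), ax], seg2d[min(b + 1, seg_len - 1), ax]],
            )
        smooth = savgol_smooth(
            UniformSeries(0.0, grf.fs, cleaned), savgol_window, 3
        ).values
        w = np.ones(seg_len)
        nb = min(blend_samples, seg_len // 2)
        if nb > 0:
            ramp = np.linspace(0.0, 1.0, nb + 2)[1:-1]
            w[:nb] = ramp
            w[seg_len - nb:] = ramp[::-1]
        repl = w[:, None] * smooth + (1.0 - w[:, None]) * seg2d
        out[lo:hi] = repl if seg.ndim == 2 else repl[:, 0]
    return grf.with_values(out)


def filter_grf_axes(
    grf: UniformSeries,
    band_x_hz=(0.1, 5.0),
    band_y_hz=(0.1, 3.0),
    lowpass_z_hz: float = 10.0,
) -> UniformSeries:
    """Axis-specific zero-phase filtering of the 3D force estimate.

    The 0.1 Hz high edge on the shear axes removes the (unobservable) DC
    shear leak; the 10 Hz low-pass on Z keeps the full weight-support DC.
    """
    if grf.fs <= 20.0:
        raise InvalidParameterError("axis filtering requires fs > 20 Hz")
    if not grf.is_vector:
        raise InvalidParameterError("filter_grf_axes expects a 3-vector series")
    x = UniformSeries(grf.t0, grf.fs, grf.values[:, 0])
    y = UniformSeries(grf.t0, grf.fs, grf.values[:, 1])
    z = UniformSeries(grf.t0, grf.fs, grf.values[:, 2])
    fx = butter_zero_phase(x, "band", band_x_hz, order=2).values
    fy = butter_zero_phase(y, "band", band_y_hz, order=2).values
    fz = butter_zero_phase(z, "low", lowpass_z_hz, order=2).values
    return grf.with_values(np.column_stack([fx, fy, fz]))


def run_frame_chain(
    imu_p: ImuRecording,
    segmentation: StepSegmentation,
    r_init: np.ndarray,
    bias_init: np.ndarray,
    eekf_cfg: EekfConfig | None = None,
    gravity: float = GRAVITY,
    heading_min_speed: float = DEFAULT_MIN_HEADING_SPEED,
    heading_rel_speed_frac: float = DEFAULT_REL_SPEED_FRAC,
) -> tuple[UniformSeries, list[StepFrame], RotationSequence]:
    """Track orientation and apply per-step frame updates.

    Returns the full-length acceleration series expressed, per step, in that
    step's own initial-contact frame, together with the per-step frames.
    Samples before the first contact stay in the initial frame; samples
    after the last contact stay in the last frame.

    The filter itself runs once in the initial frame: frame updates are
    pure yaws applied from the left, which change neither the body-frame
    prediction nor the inclination innovation, so they commute with the
    filtering and are applied as a cumulative rotation afterwards.
    """
    eekf_cfg = eekf_cfg or EekfConfig()
    r_seq = track_orientation(imu_p, r_init, bias_init, eekf_cfg)
    acc0 = transform_to_previous_frame(imu_p.accel, r_seq)

    out = np.empty_like(acc0.values)
    frames: list[StepFrame] = []
    cum = np.eye(3)
    fs = imu_p.fs
    t0 = imu_p.accel.t0
    bounds = [imu_p.accel.index_at(t) for t in segmentation.ic_times]
    bounds = [min(max(b, 0), imu_p.n) for b in bounds]

    first = bounds[0] if bounds else imu_p.n
    out[:first] = acc0.values[:first]

    # candidate headings per step, computed once in the initial frame (the
    # per-step velocity is yaw-equivariant, so the screen is chain-free)
    cands = collect_step_headings(
        ("accel", acc0.values), bounds, fs, gravity,
        heading_min_speed, heading_rel_speed_frac,
    )
    for k, (i0, i1) in enumerate(zip(bounds[:-1], bounds[1:])):
        c = cands[k]
        if c is None:
            # reuse the previous heading: identity update keeps continuity
            r_upd = np.eye(3)
            frames.append(StepFrame(k, r_upd, None, None, degenerate=True))
        else:
            h0, m, speed = c
            h_prev = cum[:2, :2] @ h0  # heading in frame ic(k-1)
            h_prev = h_prev / np.linalg.norm(h_prev)
            r_upd = frame_update_rotation(h_prev)
            frames.append(StepFrame(k, r_upd, h_prev, m, peak_speed=speed))
        cum = r_upd @ cum
        out[i0:i1] = acc0.values[i0:i1] @ cum.T

    last = bounds[-1] if bounds else imu_p.n
    if last < imu_p.n:
        out[last:] = acc0.values[last:] @ cum.T

    return UniformSeries(t0, fs, out), frames, r_seq


def run_pipeline(
    imu_s: ImuRecording,
    calib: CalibrationResult,
    mass: float,
    cfg: GrfConfig | None = None,
) -> GrfEstimate:
    """Run the full IMU-only chain on a sensor-frame recording."""
    cfg = cfg or GrfConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # annotate with the failing stage
            raise PipelineStageError(name, exc) from exc

    imu_p = stage("sensor-to-pelvis", imu_s.rotated, calib.r_ps, "pelvis")
    seg = stage(
        "initial-contact detection",
        detect_initial_contacts,
        imu_p.accel,
        min_prominence=cfg.ic_min_prominence,
        lp_cutoff_hz=cfg.ic_lp_cutoff_hz,
        ic_offset_s=cfg.ic_offset_s,
        min_interval_s=cfg.ic_min_interval_s,
    )
    try:
        r_init = bootstrap_initial_heading(
            imu_p, cfg.eekf, cfg.n_boot_steps, segmentation=seg,
            bias_init=calib.gyro_bias_init,
        )
    except BootstrapError:
        # too few steps (e.g. quiet standing): heading is arbitrary anyway
        r_init = initial_tilt_from_accel(imu_p)

    acc_ic, frames, r_seq = stage(
        "orientation + step frames",
        run_frame_chain,
        imu_p, seg, r_init, calib.gyro_bias_init, cfg.eekf, cfg.gravity,
        cfg.heading_min_speed, cfg.heading_rel_speed_frac,
    )
    grf_raw = stage("newton", compute_raw_grf, acc_ic, mass)
    grf_clean = stage(
        "impact-peak removal",
        remove_impact_peaks,
        grf_raw, seg.ic_times, cfg.peak_half_window_s, cfg.peak_savgol_window,
    )
    grf_filt = stage(
        "axis filtering",
        filter_grf_axes,
        grf_clean, cfg.band_x_hz, cfg.band_y_hz, cfg.lowpass_z_hz,
    )
    pbw = grf_filt.with_values(100.0 * grf_filt.values / (mass * cfg.gravity))
    return GrfEstimate(
        grf_n=grf_filt,
        grf_pbw=pbw,
        segmentation=seg,
        frames=frames,
        mass=mass,
        rotation_seq=r_seq,
    )
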