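"""Reference processing chain: instrumented shoes + optical markers.

The reference total GRF is the sum of the per-foot force streams; initial
contacts are threshold crossings (30 N) of each foot's force magnitude.
CoM kinematics come from the centroid of four pelvis markers, differentiated
and low-pass filtered; the same high-frequency-velocity heading construction
as the IMU path then expresses the reference force in per-step body-centric
frames, so the two systems are compared like for like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, TooShortError
from .orientation_eekf import GRAVITY
from .recordings import FootForceRecording, MarkerRecording
from .signalproc import (
    UniformSeries,
    butter_zero_phase,
    differentiate,
    integrate_cumulative,
)
from .step_frames import (
    DEFAULT_MIN_HEADING_SPEED,
    DEFAULT_REL_SPEED_FRAC,
    StepFrame,
    collect_step_headings,
    frame_update_rotation,
)

__all__ = [
    "ReferenceResult",
    "sum_forceshoe",
    "detect_ic_force",
    "com_from_markers",
    "reference_com_kinematics",
    "reference_grf_in_ic_frame",
    "run_reference_pipeline",
]


@dataclass
class ReferenceResult:
    grf_ic_n: UniformSeries
    grf_ic_pbw: UniformSeries | None
    ic_times: np.ndarray
    frames: list[StepFrame] = field(default_factory=list)


def sum_forceshoe(rec: FootForceRecording) -> UniformSeries:
    """Total reference GRF: elementwise left + right foot force."""
    if rec.left.n != rec.right.n:
        raise InvalidParameterError("left/right force length mismatch")
    return rec.left.with_values(rec.left.values + rec.right.values)


def detect_ic_force(
    foot_force: UniformSeries, threshold: float = 30.0,
    refractory_s: float = 0.1,
) -> np.ndarray:
    """Initial contacts as upward crossings of the per-foot force magnitude
    through ``threshold`` newtons, debounced by a refractory interval."""
    mag = np.linalg.norm(foot_force.values, axis=1) if foot_force.is_vector \
        else np.abs(foot_force.values)
    above = mag >= threshold
    crossings = np.flatnonzero(above & ~np.roll(above, 1))
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings[crossings != 0]])
    times = foot_force.t0 + crossings / foot_force.fs
    kept: list[float] = []
    for tt in times:
        if not kept or tt - kept[-1] >= refractory_s:
            kept.append(float(tt))
    return np.asarray(kept)


def com_from_markers(markers: MarkerRecording) -> UniformSeries:
    """CoM position as the centroid of the four pelvis markers."""
    series = list(markers.markers.values())
    vals = np.mean([s.values for s in series], axis=0)
    return series[0].with_values(vals)


def fill_marker_gaps(values: np.ndarray, fs: float, max_gap_s: float = 0.1
                     ) -> np.ndarray:
    """Linear interpolation of NaN gaps no longer than ``max_gap_s``.

    Operates on a raw array (a :class:`UniformSeries` never holds NaN):
    the gap policy is applied while reading marker files, before the typed
    container is built.  Longer gaps are an error — dropped-marker trials
    are excluded rather than fabricated.
    """
    vals = np.array(values, dtype=float)
    if np.all(np.isfinite(vals)):
        return vals
    flat = vals if vals.ndim == 2 else vals[:, None]
    bad = ~np.isfinite(flat).all(axis=1)
    run, longest = 0, 0
    for b in bad:
        run = run + 1 if b else 0
        longest = max(longest, run)
    if longest / fs > max_gap_s:
        raise InvalidParameterError(
            f"marker gap of {longest / fs:.3f} s exceeds "
            f"{max_gap_s} s fill limit"
        )
    idx = np.arange(flat.shape[0])
    for c in range(flat.shape[1]):
        col = flat[:, c]
        ok = np.isfinite(col)
        flat[:, c] = np.interp(idx, idx[ok], col[ok])
    return vals


def reference_com_kinematics(
    com_pos: UniformSeries, gravity: float = GRAVITY,
    lp_cutoff_hz: float = 10.0, hp_cutoff_hz: float = 2.0,
) -> tuple[UniformSeries, UniformSeries]:
    """CoM specific force and high-frequency velocity from marker positions.

    Acceleration: double differentiation, 10 Hz zero-phase low-pass, then
    the gravitational reaction added to Z so the series matches the IMU's
    specific-force convention ((0, 0, +g) at rest).  Velocity: the gravity
    term is removed again, the series integrated and 2 Hz high-passed —
    mirroring the IMU path so both body-centric frames are built alike.
    """
    if com_pos.n < 10:
        raise TooShortError("marker stream too short for kinematics")
    acc_raw = differentiate(differentiate(com_pos))
    acc_lp = butter_zero_phase(acc_raw, "low", lp_cutoff_hz, order=2)
    g_vec = np.array([0.0, 0.0, gravity])
    com_acc = acc_lp.with_values(acc_lp.values + g_vec)
    vel = integrate_cumulative(acc_lp)
    vel_hf = butter_zero_phase(vel, "high", hp_cutoff_hz, order=2)
    return com_acc, vel_hf


def reference_grf_in_ic_frame(
    total_grf: UniformSeries,
    com_vel_hf: UniformSeries,
    ic_times,
    heading_min_speed: float = DEFAULT_MIN_HEADING_SPEED,
    rel_speed_frac: float = DEFAULT_REL_SPEED_FRAC,
) -> tuple[UniformSeries, list[StepFrame]]:
    """Express the summed reference GRF in per-step body-centric frames.

    The per-step heading is the direction of the high-frequency CoM velocity
    at its horizontal peak inside each step, exactly as in the IMU path.
    Steps whose peak horizontal speed falls below ``heading_min_speed``
    (standing spans between the force-threshold contacts) reuse the previous
    heading.  The chain is anchored on the most vigorous step so the steady
    walking direction maps to +X, mirroring the IMU path's bootstrap.
    """
    if total_grf.n != com_vel_hf.n:
        raise InvalidParameterError("force and velocity streams not aligned")
    ic = np.asarray(ic_times, dtype=float)
    out = total_grf.values.copy()
    frames: list[StepFrame] = []
    if ic.size < 2:
        return total_grf.with_values(out), frames

    bounds = [min(max(total_grf.index_at(tt), 0), total_grf.n) for tt in ic]

    # per-step headings straight from the (global-frame) marker velocity
    headings_g = collect_step_headings(
        ("velocity", com_vel_hf.values), bounds, com_vel_hf.fs, 0.0,
        heading_min_speed, rel_speed_frac,
    )

    usable = [hg for hg in headings_g if hg is not None]
    if usable:
        anchor = max(usable, key=lambda hg: hg[2])
        cum = frame_update_rotation(anchor[0])
    else:
        cum = np.eye(3)

    out[: bounds[0]] = total_grf.values[: bounds[0]] @ cum.T
    for k, (i0, i1) in enumerate(zip(bounds[:-1], bounds[1:])):
        hg = headings_g[k]
        if hg is None:
            r_upd = np.eye(3)
            frames.append(StepFrame(k, r_upd, None, None, degenerate=True))
        else:
            h_prev = cum[:2, :2] @ hg[0]  # heading in frame ic(k-1)
            h_prev = h_prev / np.linalg.norm(h_prev)
            r_upd = frame_update_rotation(h_prev)
            frames.append(StepFrame(k, r_upd, h_prev, hg[1],
                                    peak_speed=hg[2]))
        cum = r_upd @ cum
        out[i0:i1] = total_grf.values[i0:i1] @ cum.T
    out[bounds[-1]:] = total_grf.values[bounds[-1]:] @ cum.T
    return total_grf.with_values(out), frames


def run_reference_pipeline(
    forces: FootForceRecording,
    markers: MarkerRecording,
    mass: float | None = None,
    gravity: float = GRAVITY,
    ic_threshold_n: float = 30.0,
) -> ReferenceResult:
    """Full reference chain: sum forces, detect contacts, marker kinematics,
    body-centric transform."""
    total = sum_forceshoe(forces)
    ic_left = detect_ic_force(forces.left, ic_threshold_n)
    ic_right = detect_ic_force(forces.right, ic_threshold_n)
    ic = np.sort(np.concatenate([ic_left, ic_right]))
    # merge near-simultaneous double counts
    if ic.size:
        keep = np.concatenate([[True], np.diff(ic) >= 0.1])
        ic = ic[keep]
    com = com_from_markers(markers)
    _, vel_hf = reference_com_kinematics(com, gravity)
    grf_ic, frames = reference_grf_in_ic_frame(total, vel_hf, ic)
    pbw = None
    if mass is not None:
        pbw = grf_ic.with_values(100.0 * grf_ic.values / (mass * gravity))
    return ReferenceResult(
        grf_ic_n=grf_ic, grf_ic_pbw=pbw, ic_times=ic, frames=frames
    )
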