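"""Per-step body-centric "initial contact" frame construction.

Within a step (the interval between consecutive initial contacts) the pelvis
accelerations — expressed in the previous step's frame — are integrated and
high-pass filtered to the high-frequency CoM velocity.  The horizontal
direction of that velocity at its peak defines the new frame's forward (X)
axis; the vertical is kept global, so the frame update is a pure yaw.  This
makes the whole downstream force estimate body-centric: it never references
a fixed global heading and is therefore magnetometer-free and immune to
heading drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHeadingError, InvalidParameterError, TooShortError
from .orientation_eekf import GRAVITY, RotationSequence
from .signalproc import UniformSeries, butter_zero_phase, integrate_cumulative

__all__ = [
    "StepFrame",
    "transform_to_previous_frame",
    "com_velocity_highfreq",
    "step_heading",
    "frame_update_rotation",
]

MIN_STEP_SAMPLES = 8  # shortest step the 2 Hz zero-phase high-pass can handle

# Steps whose peak horizontal velocity falls below this are treated as
# degenerate (heading carried over).  Quiet standing with sensor noise never
# yields exactly zero velocity, so the degenerate fallback needs a physical
# threshold: 0.05 m/s is far below the ~0.1-0.2 m/s within-step fluctuation
# of actual walking but above integrated noise and initiation dribble.
DEFAULT_MIN_HEADING_SPEED = 0.05  # m/s

# A step's heading is trusted only when its peak horizontal velocity is
# comparable to the trial's strongest step: initiation and termination
# fragments carry genuine backward high-frequency velocity (deceleration)
# that would yield wildly rotated frames.
DEFAULT_REL_SPEED_FRAC = 0.5


def collect_step_headings(
    vel_source,
    bounds: list[int],
    fs: float,
    gravity: float,
    min_speed: float = DEFAULT_MIN_HEADING_SPEED,
    rel_speed_frac: float = DEFAULT_REL_SPEED_FRAC,
    exclude_first_last: bool = True,
) -> list[tuple[np.ndarray, int, float] | None]:
    """Candidate headings for every step window, with the validity screen.

    ``vel_source`` is either a precomputed high-frequency velocity array
    (used as-is per window) or an acceleration array from which the per-step
    velocity is derived (integrate + high-pass, the IMU path).  Entries are
    (heading_xy, m_index, peak_speed) or None for degenerate steps.  Both
    screens are applied: the absolute floor and the trial-relative fraction.
    The first and last steps of a trial straddle gait initiation and
    termination, where the high-frequency velocity points backward
    (deceleration) or is still ramping up; when the trial has more than two
    steps their headings are not trusted either.
    """
    kind, arr = vel_source
    cands: list[tuple[np.ndarray, int, float] | None] = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        try:
            seg = UniformSeries(0.0, fs, arr[i0:i1])
            vel = seg if kind == "velocity" else com_velocity_highfreq(
                seg, gravity
            )
            h, m = step_heading(vel, eps=min_speed)
            speed = float(np.linalg.norm(vel.values[m, :2]))
            cands.append((h, m, speed))
        except (DegenerateHeadingError, TooShortError):
            cands.append(None)
    speeds = [c[2] for c in cands if c is not None]
    if speeds:
        floor = rel_speed_frac * max(speeds)
        cands = [c if (c is not None and c[2] >= floor) else None
                 for c in cands]
    if exclude_first_last and len(cands) > 2:
        cands[0] = None
        cands[-1] = None
    return cands


@dataclass
class StepFrame:
    """Frame update for step k: a pure yaw mapping frame k-1 onto frame k.

    ``heading_xy`` is the unit horizontal CoM-velocity direction in the
    previous frame's coordinates (None when the step was degenerate and the
    previous heading was reused), ``m_index`` the step-local sample index of
    maximal horizontal velocity.
    """

    k: int
    r_update: np.ndarray
    heading_xy: np.ndarray | None
    m_index: int | None
    degenerate: bool = False
    peak_speed: float | None = None  # horizontal speed at m, m/s


def transform_to_previous_frame(
    acc_p: UniformSeries, r_seq: RotationSequence
) -> UniformSeries:
    """Rotate pelvis-frame accelerations into the step's reference frame,
    sample by sample: y_i' = R_i @ y_i."""
    if acc_p.n != r_seq.n:
        raise InvalidParameterError(
            f"rotation sequence covers {r_seq.n} samples, series has {acc_p.n}"
        )
    out = np.einsum("nij,nj->ni", r_seq.r, acc_p.values)
    return acc_p.with_values(out)


def com_velocity_highfreq(
    acc_ic: UniformSeries, gravity: float = GRAVITY, cutoff_hz: float = 2.0
) -> UniformSeries:
    """High-frequency CoM velocity from specific force in a level frame.

    Subtracts the gravity constant, integrates from zero, then high-passes
    (2 Hz, order 2, zero phase).  The high-pass annihilates any constant of
    integration and slow drift, so the arbitrary initial velocity does not
    matter.  A short filter pad (3 x order) keeps the edge transient local:
    a step window spans well under one period of the 2 Hz cutoff, so a long
    mirrored extension would swamp the window with reflected integration
    drift.  The transient-bearing edge samples are excluded from the heading
    search downstream.
    """
    if acc_ic.n < MIN_STEP_SAMPLES:
        raise TooShortError(
            f"step of {acc_ic.n} samples too short for velocity estimation"
        )
    lin = acc_ic.values - np.array([0.0, 0.0, gravity])
    vel = integrate_cumulative(acc_ic.with_values(lin))
    return butter_zero_phase(vel, "high", cutoff_hz, order=2, padlen=6)


HEADING_EDGE_EXCLUDE = 6  # zero-phase warm-up samples (3 x filter order)


def step_heading(vel: UniformSeries, eps: float = 1e-6,
                 edge_exclude: int = HEADING_EDGE_EXCLUDE
                 ) -> tuple[np.ndarray, int]:
    """Unit horizontal velocity direction at the instant of maximal
    horizontal speed within the step; ties break to the first index.

    The first/last ``edge_exclude`` samples are skipped in the search when
    the step is long enough: the zero-phase filter's warm-up region is not
    trustworthy and the physical velocity peak is interior to the step.
    """
    horiz = vel.values[:, :2]
    speed = np.linalg.norm(horiz, axis=1)
    lo = edge_exclude if vel.n > 3 * edge_exclude else 0
    hi = vel.n - lo
    m = lo + int(np.argmax(speed[lo:hi]))
    if speed[m] <= eps:
        raise DegenerateHeadingError(
            "no horizontal CoM velocity in step (all-vertical or zero)"
        )
    return horiz[m] / speed[m], m


def frame_update_rotation(heading_xy: np.ndarray) -> np.ndarray:
    """Pure-yaw coordinate rotation taking ``heading_xy`` to +X.

    Rows are the new frame's axes in the old frame's coordinates:
    X = (hx, hy, 0), Y = Z x X, Z = (0, 0, 1); hence
    R @ (hx, hy, 0)^T = (1, 0, 0)^T.
    """
    h = np.asarray(heading_xy, dtype=float)
    if h.shape != (2,) or not np.isclose(np.linalg.norm(h), 1.0, atol=1e-6):
        raise InvalidParameterError("heading must be a unit 2-vector")
    hx, hy = h
    return np.array(
        [[hx, hy, 0.0], [-hy, hx, 0.0], [0.0, 0.0, 1.0]]
    )
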