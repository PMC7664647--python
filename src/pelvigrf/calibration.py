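"""Sensor-to-pelvis calibration from standing and forward bowing.

The protocol provides exactly two motions before walking: a quiet stance and
three forward trunk bows.  Standing fixes the vertical (the accelerometer
reads specific force +g upward at rest) and gives the initial gyroscope
bias; bowing excites rotation about the pelvis mediolateral axis, which
fixes the remaining heading degree of freedom of the sensor mounting.

Conventions: pelvis frame is right-handed with X forward (anterior),
Y left, Z up.  A forward bow is a positive rotation about +Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateCalibrationError, NotStillError
from .recordings import ImuRecording
from .signalproc import UniformSeries, butter_zero_phase

__all__ = ["CalibrationResult", "estimate_gyro_bias", "bowing_calibration",
           "detect_bow_windows"]

_AXIS_NAMES = "xyz"


@dataclass
class CalibrationResult:
    """Outcome of the standing + bowing calibration.

    ``r_ps`` rotates sensor-frame vectors into the pelvis frame
    (v_p = r_ps @ v_s); its rows are the pelvis X, Y, Z axes expressed in
    sensor coordinates.  ``gyro_bias_init`` is the stance-window gyroscope
    mean, used to seed the orientation filter's bias state.
    """

    r_ps: np.ndarray
    gyro_bias_init: np.ndarray
    still_window: tuple[float, float]
    bow_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        r = np.asarray(self.r_ps, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(r), 1.0, atol=1e-9
        ):
            raise DegenerateCalibrationError("r_ps is not a proper rotation")
        self.r_ps = r
        self.gyro_bias_init = np.asarray(self.gyro_bias_init, dtype=float)


def estimate_gyro_bias(
    gyro: UniformSeries, stillness_threshold: float = 0.05
) -> np.ndarray:
    """Per-axis mean angular rate over a stance window, rad/s.

    Raises :class:`NotStillError` (naming the offending axis) if any axis
    shows a standard deviation above ``stillness_threshold`` — the window
    then contains motion and its mean is not a bias.
    """
    if gyro.n < max(2, int(0.5 * gyro.fs)):
        raise NotStillError("stillness window shorter than 0.5 s")
    std = gyro.values.std(axis=0)
    bad = np.nonzero(std > stillness_threshold)[0]
    if bad.size:
        names = ", ".join(_AXIS_NAMES[i] for i in bad)
        raise NotStillError(
            f"gyroscope axis {names} not still (std {std[bad]} rad/s "
            f"> {stillness_threshold})"
        )
    return gyro.values.mean(axis=0)


def detect_bow_windows(
    imu: ImuRecording,
    search_start: float,
    search_stop: float,
    rate_threshold: float = 0.3,
    min_gap_s: float = 0.3,
    max_windows: int = 3,
) -> list[tuple[float, float]]:
    """Auto-detect bow windows as the largest |angular rate| bursts.

    A convenience only — explicitly supplied windows are authoritative.
    """
    gyro = imu.gyro.slice_time(search_start, search_stop)
    mag = UniformSeries(gyro.t0, gyro.fs, np.linalg.norm(gyro.values, axis=1))
    smooth = butter_zero_phase(mag, "low", 3.0, order=2)
    active = smooth.values > rate_threshold
    edges = np.flatnonzero(np.diff(active.astype(int)))
    starts = list(edges[~active[edges]] + 1) if edges.size else []
    stops = list(edges[active[edges]] + 1) if edges.size else []
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        stops.append(smooth.n)
    regions = list(zip(starts, stops))
    # merge regions separated by less than min_gap_s
    merged: list[list[int]] = []
    for a, b in regions:
        if merged and (a - merged[-1][1]) / gyro.fs < min_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    scored = [
        (float(smooth.values[a:b].max()), a, b) for a, b in merged
    ]
    scored.sort(reverse=True)
    picked = sorted((a, b) for _, a, b in scored[:max_windows])
    return [(gyro.t0 + a / gyro.fs, gyro.t0 + b / gyro.fs) for a, b in picked]


def bowing_calibration(
    imu: ImuRecording,
    still_window: tuple[float, float],
    bow_windows: list[tuple[float, float]],
    stillness_threshold: float = 0.05,
    min_bow_rate: float = 0.3,
    degenerate_angle_deg: float = 15.0,
) -> CalibrationResult:
    """Estimate the sensor-to-pelvis rotation from stance + forward bows.

    Construction: the pelvis +Z axis (in sensor coordinates) is the
    normalised mean accelerometer vector over the stance window; the
    mediolateral (+Y, left) axis is the first principal direction of the
    gyroscope samples over the bow windows, signed so that the first bow
    starts with positive rotation about +Y (forward pitch); Y is
    orthogonalised against Z and X = Y x Z completes the right-handed triad.
    """
    if imu.frame != "sensor":
        raise DegenerateCalibrationError("calibration expects sensor-frame data")
    still = imu.slice_time(*still_window)
    bias = estimate_gyro_bias(still.gyro, stillness_threshold)

    z_s = still.accel.values.mean(axis=0)
    z_s = z_s / np.linalg.norm(z_s)

    if not bow_windows:
        raise DegenerateCalibrationError("no bow windows supplied")
    gyro_chunks = [
        imu.gyro.slice_time(a, b).values - bias for (a, b) in bow_windows
    ]
    bow = np.vstack(gyro_chunks)
    peak_rate = np.linalg.norm(bow, axis=1).max()
    if peak_rate < min_bow_rate:
        raise DegenerateCalibrationError(
            f"bow windows contain no dominant rotation "
            f"(peak |omega| {peak_rate:.3f} < {min_bow_rate} rad/s)"
        )
    # first principal direction of the (uncentred) bow angular rates
    _, _, vt = np.linalg.svd(bow, full_matrices=False)
    axis = vt[0]
    # sign: the first bow must begin with positive rotation about +Y
    w0 = gyro_chunks[0] @ axis
    lead = np.nonzero(np.abs(w0) > 0.5 * np.abs(w0).max())[0][0]
    if w0[lead] < 0:
        axis = -axis

    cos_to_vertical = abs(float(np.dot(axis, z_s)))
    if cos_to_vertical > np.cos(np.radians(degenerate_angle_deg)):
        raise DegenerateCalibrationError(
            "bowing axis within "
            f"{degenerate_angle_deg} deg of vertical; bow indistinguishable "
            "from a turn"
        )

    y_s = axis - np.dot(axis, z_s) * z_s
    y_s = y_s / np.linalg.norm(y_s)
    x_s = np.cross(y_s, z_s)
    r_ps = np.vstack([x_s, y_s, z_s])
    return CalibrationResult(
        r_ps=r_ps,
        gyro_bias_init=bias,
        still_window=tuple(still_window),
        bow_windows=[tuple(w) for w in bow_windows],
    )
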