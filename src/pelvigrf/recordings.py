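"""Typed containers for the raw measurement streams."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .signalproc import UniformSeries

MARKER_NAMES = ("RASI", "RPSI", "LASI", "LPSI")


@dataclass
class ImuRecording:
    """Synchronised accelerometer + gyroscope streams from one IMU.

    ``accel`` holds specific force in m/s^2 (reads +g upward at rest),
    ``gyro`` angular velocity in rad/s.  ``frame`` tags the coordinate
    frame: "sensor" before calibration, "pelvis" after.
    """

    accel: UniformSeries
    gyro: UniformSeries
    frame: str = "sensor"

    def __post_init__(self):
        if not (self.accel.is_vector and self.gyro.is_vector):
            raise InvalidParameterError("IMU streams must be 3-vector series")
        if self.accel.n != self.gyro.n or self.accel.fs != self.gyro.fs:
            raise InvalidParameterError("accel and gyro must be aligned")
        if self.frame not in ("sensor", "pelvis"):
            raise InvalidParameterError(f"unknown frame tag {self.frame!r}")

    @property
    def fs(self) -> float:
        return self.accel.fs

    @property
    def n(self) -> int:
        return self.accel.n

    def rotated(self, r: np.ndarray, frame: str) -> "ImuRecording":
        """Re-express both streams through rotation ``r`` (v' = r @ v)."""
        return ImuRecording(
            accel=self.accel.with_values(self.accel.values @ np.asarray(r).T),
            gyro=self.gyro.with_values(self.gyro.values @ np.asarray(r).T),
            frame=frame,
        )

    def slice_time(self, start: float, stop: float) -> "ImuRecording":
        return ImuRecording(
            accel=self.accel.slice_time(start, stop),
            gyro=self.gyro.slice_time(start, stop),
            frame=self.frame,
        )


@dataclass
class FootForceRecording:
    """Per-foot 3D ground reaction force streams, in newtons."""

    left: UniformSeries
    right: UniformSeries

    def __post_init__(self):
        if self.left.n != self.right.n or self.left.fs != self.right.fs:
            raise InvalidParameterError("left/right force streams must be aligned")
        if not (self.left.is_vector and self.right.is_vector):
            raise InvalidParameterError("force streams must be 3-vector series")

    @property
    def fs(self) -> float:
        return self.left.fs


@dataclass
class MarkerRecording:
    """Four pelvis marker trajectories (metres): RASI, RPSI, LASI, LPSI."""

    markers: dict[str, UniformSeries]

    def __post_init__(self):
        missing = [m for m in MARKER_NAMES if m not in self.markers]
        if missing:
            raise InvalidParameterError(f"missing markers: {missing}")
        lens = {s.n for s in self.markers.values()}
        rates = {s.fs for s in self.markers.values()}
        if len(lens) != 1 or len(rates) != 1:
            raise InvalidParameterError("marker trajectories must be aligned")

    @property
    def fs(self) -> float:
        return next(iter(self.markers.values())).fs
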