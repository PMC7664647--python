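"""CSV schemas, run configuration, and JSON report helpers.

All files are plain comma-separated text with a mandatory header row, dot
decimals, and a time column in seconds.  The time base must be strictly
increasing and uniform within 1 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .recordings import MARKER_NAMES, FootForceRecording, ImuRecording, MarkerRecording
from .signalproc import UniformSeries

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
FORCE_COLUMNS = ["t", "side", "fx", "fy", "fz"]
MARKER_COLUMNS = ["t", "name", "x", "y", "z"]
GRF_COLUMNS = ["t", "fx_n", "fy_n", "fz_n", "fx_pbw", "fy_pbw", "fz_pbw"]


def _validate_time(t: np.ndarray, path) -> tuple[float, float]:
    if t.size < 2:
        raise SchemaError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SchemaError(f"{path}: time column not strictly increasing")
    mean_dt = float(dt.mean())
    if np.max(np.abs(dt - mean_dt)) > 1e-6 * max(mean_dt, 1.0) + 1e-9:
        raise SchemaError(f"{path}: sample rate not uniform within 1 ppm")
    return float(t[0]), 1.0 / mean_dt


def _check_finite(df: pd.DataFrame, cols, path):
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy()))[0]
        if bad.size:
            raise SchemaError(
                f"{path}: non-finite value in column '{c}' at row {bad[0]}"
            )


def _read_csv(path, required_cols) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def read_imu_csv(path) -> ImuRecording:
    df = _read_csv(path, IMU_COLUMNS)
    _check_finite(df, [c for c in IMU_COLUMNS if c != "t"], path)
    t0, fs = _validate_time(df["t"].to_numpy(float), path)
    accel = UniformSeries(t0, fs, df[["ax", "ay", "az"]].to_numpy(float))
    gyro = UniformSeries(t0, fs, df[["gx", "gy", "gz"]].to_numpy(float))
    return ImuRecording(accel=accel, gyro=gyro, frame="sensor")


def write_imu_csv(path, imu: ImuRecording):
    df = pd.DataFrame(
        np.column_stack([imu.accel.t, imu.accel.values, imu.gyro.values]),
        columns=IMU_COLUMNS,
    )
    with open(path, "w") as fh:
        fh.write("# t: s; ax..az: specific force m/s^2; gx..gz: rad/s\n")
        df.to_csv(fh, index=False)


def read_force_csv(path) -> FootForceRecording:
    df = _read_csv(path, FORCE_COLUMNS)
    _check_finite(df, ["fx", "fy", "fz"], path)
    sides = {}
    for side in ("L", "R"):
        sub = df[df["side"] == side]
        if sub.empty:
            raise SchemaError(f"{path}: no rows for side '{side}'")
        t0, fs = _validate_time(sub["t"].to_numpy(float), path)
        sides[side] = UniformSeries(t0, fs, sub[["fx", "fy", "fz"]].to_numpy(float))
    return FootForceRecording(left=sides["L"], right=sides["R"])


def write_force_csv(path, forces: FootForceRecording):
    rows = []
    for side, s in (("L", forces.left), ("R", forces.right)):
        rows.append(pd.DataFrame({
            "t": s.t, "side": side,
            "fx": s.values[:, 0], "fy": s.values[:, 1], "fz": s.values[:, 2],
        }))
    df = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write("# t: s; side: L|R; fx..fz: N (per-foot ground reaction)\n")
        df.to_csv(fh, index=False)


def read_marker_csv(path) -> MarkerRecording:
    """Read marker trajectories; NaN gaps up to 0.1 s are linearly filled
    (the documented gap policy), longer gaps are a schema error."""
    from .reference_pipeline import fill_marker_gaps

    df = _read_csv(path, MARKER_COLUMNS)
    markers = {}
    for name in MARKER_NAMES:
        sub = df[df["name"] == name]
        if sub.empty:
            raise SchemaError(f"{path}: missing marker '{name}'")
        t0, fs = _validate_time(sub["t"].to_numpy(float), path)
        vals = sub[["x", "y", "z"]].to_numpy(float)
        try:
            vals = fill_marker_gaps(vals, fs)
        except Exception as exc:
            raise SchemaError(f"{path}: marker '{name}': {exc}") from exc
        markers[name] = UniformSeries(t0, fs, vals)
    return MarkerRecording(markers=markers)


def write_marker_csv(path, markers: MarkerRecording):
    rows = []
    for name, s in markers.markers.items():
        rows.append(pd.DataFrame({
            "t": s.t, "name": name,
            "x": s.values[:, 0], "y": s.values[:, 1], "z": s.values[:, 2],
        }))
    df = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write("# t: s; name: pelvis marker; x,y,z: m (global frame)\n")
        df.to_csv(fh, index=False)


def read_marker_c3d(path) -> MarkerRecording:
    """Optional import of marker trajectories from a C3D file (requires the
    ezc3d package)."""
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise SchemaError("C3D import requires the optional ezc3d package") from exc
    c3d = ezc3d.c3d(str(path))
    labels = [l.strip() for l in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    fs = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    markers = {}
    for name in MARKER_NAMES:
        if name not in labels:
            raise SchemaError(f"{path}: missing marker '{name}'")
        i = labels.index(name)
        xyz = pts[:3, i, :].T / 1000.0  # mm -> m
        markers[name] = UniformSeries(0.0, fs, xyz)
    return MarkerRecording(markers=markers)


def write_grf_csv(path, grf_n: UniformSeries, grf_pbw: UniformSeries):
    df = pd.DataFrame(
        np.column_stack([grf_n.t, grf_n.values, grf_pbw.values]),
        columns=GRF_COLUMNS,
    )
    with open(path, "w") as fh:
        fh.write("# t: s; fx_n..fz_n: N; fx_pbw..fz_pbw: % body weight; "
                 "body-centric per-step frame (X forward, Z up)\n")
        df.to_csv(fh, index=False)


def read_grf_csv(path) -> tuple[UniformSeries, UniformSeries]:
    df = _read_csv(path, GRF_COLUMNS)
    _check_finite(df, GRF_COLUMNS[1:], path)
    t0, fs = _validate_time(df["t"].to_numpy(float), path)
    n = UniformSeries(t0, fs, df[["fx_n", "fy_n", "fz_n"]].to_numpy(float))
    pbw = UniformSeries(t0, fs, df[["fx_pbw", "fy_pbw", "fz_pbw"]].to_numpy(float))
    return n, pbw


# --------------------------------------------------------------------------
@dataclass
class RunConfig:
    """Key-value run configuration (YAML).  Unknown keys are rejected."""

    mass_kg: float = 74.3
    height_m: float | None = None
    still_window: tuple[float, float] | None = None
    bow_windows: list | None = None
    # gait events
    ic_min_prominence: float = 0.2
    ic_lp_cutoff_hz: float = 2.0
    ic_offset_s: float = 0.08
    ic_min_interval_s: float = 0.25
    n_boot_steps: int = 3
    # orientation filter
    gyro_noise_density: float = 5e-4
    bias_random_walk: float = 1e-4
    accel_meas_noise: float = 0.5
    dynamic_rejection_gate: float = 2.0
    p0_orientation: float = 1e-2
    p0_bias: float = 1e-4
    # force post-processing
    peak_half_window_s: float = 0.10
    peak_savgol_window: int = 11
    band_x_hz: tuple = (0.1, 5.0)
    band_y_hz: tuple = (0.1, 3.0)
    lowpass_z_hz: float = 10.0
    gravity: float = 9.81

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {unknown}")
        return cls(**raw)

    def grf_config(self):
        from .grf_pipeline import GrfConfig
        from .orientation_eekf import EekfConfig

        eekf = EekfConfig(
            gyro_noise_density=self.gyro_noise_density,
            bias_random_walk=self.bias_random_walk,
            accel_meas_noise=self.accel_meas_noise,
            dynamic_rejection_gate=self.dynamic_rejection_gate,
            p0_orientation=self.p0_orientation,
            p0_bias=self.p0_bias,
            gravity=self.gravity,
        )
        return GrfConfig(
            ic_min_prominence=self.ic_min_prominence,
            ic_lp_cutoff_hz=self.ic_lp_cutoff_hz,
            ic_offset_s=self.ic_offset_s,
            ic_min_interval_s=self.ic_min_interval_s,
            n_boot_steps=self.n_boot_steps,
            peak_half_window_s=self.peak_half_window_s,
            peak_savgol_window=self.peak_savgol_window,
            band_x_hz=tuple(self.band_x_hz),
            band_y_hz=tuple(self.band_y_hz),
            lowpass_z_hz=self.lowpass_z_hz,
            gravity=self.gravity,
            eekf=eekf,
        )
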