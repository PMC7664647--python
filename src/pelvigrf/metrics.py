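"""Agreement statistics between the two force estimates.

Per-axis RMS of the differences in percent body weight, Pearson correlation,
range-normalised RMS error, Bland–Altman summaries (mean difference plus
interquartile bounds — the shear-magnitude differences are not normally
distributed, so quartiles rather than limits of agreement), and the per-step
heading error between the two body-centric frames.  All statistics span the
complete trial, standing and turning included; nothing is resampled to a
gait cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidParameterError
from .orientation_eekf import GRAVITY
from .signalproc import UniformSeries

__all__ = [
    "ComparisonReport",
    "rms_diff",
    "pearson_corr",
    "nrmse",
    "bland_altman",
    "heading_error",
    "compare_grf",
]


@dataclass
class ComparisonReport:
    rms_pbw: list
    rms_magnitude_pbw: float
    corr: list
    nrmse_pct: list
    bland_altman_shear: dict
    bland_altman_vertical: dict
    theta_d_deg: list

    def to_dict(self) -> dict:
        return asdict(self)


def _check_aligned(a: UniformSeries, b: UniformSeries):
    if a.n != b.n:
        raise InvalidParameterError(
            f"series lengths differ: {a.n} vs {b.n}"
        )


def rms_diff(a: UniformSeries, b: UniformSeries, mass: float,
             gravity: float = GRAVITY) -> tuple[np.ndarray, float]:
    """Per-axis RMS of (a - b) in %BW, plus the RMS of the magnitude
    difference ||a|| - ||b||."""
    _check_aligned(a, b)
    scale = 100.0 / (mass * gravity)
    d = (a.values - b.values) * scale
    per_axis = np.sqrt(np.mean(d ** 2, axis=0))
    mag = (np.linalg.norm(a.values, axis=1)
           - np.linalg.norm(b.values, axis=1)) * scale
    return per_axis, float(np.sqrt(np.mean(mag ** 2)))


def pearson_corr(a: UniformSeries, b: UniformSeries) -> np.ndarray:
    """Product-moment correlation per axis over the whole trial.

    Axes with zero variance yield NaN (undefined), never a number."""
    _check_aligned(a, b)
    av = np.atleast_2d(a.values.T)
    bv = np.atleast_2d(b.values.T)
    out = np.full(av.shape[0], np.nan)
    for i in range(av.shape[0]):
        x, y = av[i] - av[i].mean(), bv[i] - bv[i].mean()
        sx, sy = np.sqrt(np.sum(x ** 2)), np.sqrt(np.sum(y ** 2))
        if sx > 0 and sy > 0:
            out[i] = float(np.sum(x * y) / (sx * sy))
    return out


def nrmse(a: UniformSeries, b_ref: UniformSeries) -> np.ndarray:
    """RMS error normalised by the reference range, per axis, percent."""
    _check_aligned(a, b_ref)
    rng = b_ref.values.max(axis=0) - b_ref.values.min(axis=0)
    if np.any(rng <= 0):
        raise InvalidParameterError("reference range is zero on some axis")
    rms = np.sqrt(np.mean((a.values - b_ref.values) ** 2, axis=0))
    return 100.0 * rms / rng


def bland_altman(a: UniformSeries, b: UniformSeries, plane: str,
                 mass: float | None = None, gravity: float = GRAVITY) -> dict:
    """Bland–Altman summary of a - b: mean difference and 25th/75th
    percentiles (linear interpolation).

    ``plane`` selects what is compared: "shear" pairs the horizontal-plane
    force magnitudes, "vertical" the Z components.  Values are reported in
    the input units, or %BW when ``mass`` is given.
    """
    _check_aligned(a, b)
    if plane == "shear":
        xa = np.linalg.norm(a.values[:, :2], axis=1)
        xb = np.linalg.norm(b.values[:, :2], axis=1)
    elif plane == "vertical":
        xa, xb = a.values[:, 2], b.values[:, 2]
    else:
        raise InvalidParameterError("plane must be 'shear' or 'vertical'")
    d = xa - xb
    if mass is not None:
        d = 100.0 * d / (mass * gravity)
    q1, q3 = np.percentile(d, [25.0, 75.0], method="linear")
    return {
        "mean_diff": float(np.mean(d)),
        "iqr_low": float(q1),
        "iqr_high": float(q3),
    }


def heading_error(frames_a, frames_b) -> list[float]:
    """Angle (degrees) between paired step heading vectors, interior steps
    only (first and last excluded)."""
    if len(frames_a) != len(frames_b):
        raise InvalidParameterError(
            f"step counts differ: {len(frames_a)} vs {len(frames_b)}"
        )
    if len(frames_a) < 3:
        raise InvalidParameterError("need at least 3 steps for interior angles")
    out = []
    for fa, fb in zip(frames_a[1:-1], frames_b[1:-1]):
        ha = fa.heading_xy if hasattr(fa, "heading_xy") else np.asarray(fa)
        hb = fb.heading_xy if hasattr(fb, "heading_xy") else np.asarray(fb)
        if ha is None or hb is None:
            continue
        c = float(np.clip(np.dot(ha, hb), -1.0, 1.0))
        out.append(float(np.degrees(np.arccos(c))))
    return out


def compare_grf(est: UniformSeries, ref: UniformSeries, mass: float,
                frames_est=None, frames_ref=None,
                gravity: float = GRAVITY) -> ComparisonReport:
    """Full agreement report between an estimated and a reference GRF."""
    per_axis, mag = rms_diff(est, ref, mass, gravity)
    theta = []
    if frames_est is not None and frames_ref is not None and \
            len(frames_est) == len(frames_ref) and len(frames_est) >= 3:
        theta = heading_error(frames_est, frames_ref)
    return ComparisonReport(
        rms_pbw=[float(v) for v in per_axis],
        rms_magnitude_pbw=mag,
        corr=[float(v) for v in pearson_corr(est, ref)],
        nrmse_pct=[float(v) for v in nrmse(est, ref)],
        bland_altman_shear=bland_altman(est, ref, "shear", mass, gravity),
        bland_altman_vertical=bland_altman(est, ref, "vertical", mass, gravity),
        theta_d_deg=theta,
    )
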