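"""Small SO(3) helpers shared by the orientation filter and frame logic."""

from __future__ import annotations

import numpy as np

E3 = np.array([0.0, 0.0, 1.0])


def skew(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix such that skew(a) @ b == cross(a, b)."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def exp_so3(phi: np.ndarray) -> np.ndarray:
    """Rodrigues exponential of a rotation vector (radians)."""
    angle = float(np.linalg.norm(phi))
    if angle < 1e-12:
        return np.eye(3) + skew(phi)
    axis = phi / angle
    k = skew(axis)
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def orthonormalize(r: np.ndarray) -> np.ndarray:
    """Project a nearly-orthonormal matrix onto SO(3) (polar via SVD)."""
    u, _, vt = np.linalg.svd(r)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def yaw_matrix(angle_rad: float) -> np.ndarray:
    """Rotation of coordinates by `angle_rad` about +Z."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_angle_deg(r: np.ndarray) -> float:
    """Geodesic angle of a rotation matrix, in degrees."""
    c = (np.trace(r) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def tilt_alignment(up_body: np.ndarray) -> np.ndarray:
    """Shortest rotation R with R @ up_body ∝ e3 (no rotation about vertical).

    Used to initialise the orientation filter from a static accelerometer
    sample: the measured specific-force direction is "up" in the body frame.
    """
    u = np.asarray(up_body, dtype=float)
    u = u / np.linalg.norm(u)
    axis = np.cross(u, E3)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, E3))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antipodal: rotate 180 deg about X
        return np.diag([1.0, -1.0, -1.0])
    return exp_so3(axis / s * np.arctan2(s, c))
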