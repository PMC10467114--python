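"""Small geometric primitives shared across modules: elementary rotation
matrices (degrees), angle wrapping, and minimum-image displacements for
orthorhombic boxes."""

from __future__ import annotations

import numpy as np


def rotation_x(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_y(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def compose_zyx(phi_deg: float, theta_deg: float, psi_deg: float) -> np.ndarray:
    """Tait–Bryan Z–Y–X composition ``Rz(φ) @ Ry(θ) @ Rx(ψ)``."""
    return rotation_z(phi_deg) @ rotation_y(theta_deg) @ rotation_x(psi_deg)


def wrap_angle(angle_deg):
    """Wrap angle(s) onto the half-open interval (−180, 180]."""
    wrapped = np.mod(np.asarray(angle_deg, dtype=float) + 180.0, 360.0) - 180.0
    # mod maps 180 -> -180; put it back on the closed upper end
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return wrapped if np.ndim(angle_deg) else float(wrapped)


def pose_distance(theta1, psi1, theta2, psi2):
    """√(Δθ² + Δψ²) with ψ compared on the circle (wrapped to (−180, 180])."""
    dtheta = np.asarray(theta1, dtype=float) - theta2
    dpsi = wrap_angle(np.asarray(psi1, dtype=float) - np.asarray(psi2, dtype=float))
    return np.sqrt(dtheta**2 + np.asarray(dpsi) ** 2)


def min_image_displacement(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the per-axis minimum-image convention to displacement vectors.

    ``delta`` has shape (..., 3); ``box`` is (3,) orthorhombic edge lengths or
    None (no wrapping)."""
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)
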