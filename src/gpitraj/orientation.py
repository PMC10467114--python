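"""Orientation landscape of a membrane-tethered rigid body.

The procedure: every trajectory frame is least-squares superposed (Kabsch)
onto a common reference; the resulting proper rotation is decomposed into
Tait–Bryan Z–Y–X angles

    R = Rz(φ) · Ry(θ) · Rx(ψ),   θ = −asin(R₃₁),   ψ = atan2(R₃₂/cosθ, R₃₃/cosθ)

and only (θ, ψ) — the rotations about the y- and x-axes — are kept, because
rotation φ about the membrane normal (the z-axis of the box) does not change
how the ectodomain presents itself to the membrane or to binding partners.
The pooled (θ, ψ) pairs are turned into a kernel-density landscape whose
local maxima are the preferentially adopted poses; frames nearest a mode can
be retrieved for structural inspection.

θ is confined to [−90°, 90°] by the asin branch; the mirrored solution
θ′ = 180° − θ describes the same orientation set, so a single branch already
yields a complete landscape.  At |θ| = 90° (gimbal lock, cos θ = 0) ψ and φ
are inseparable; such frames are flagged and excluded from the density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde

from .errors import AnalysisError, DegenerateBodyError, StructureError
from .geometry import pose_distance, wrap_angle
from .model import Topology, Trajectory
from .selection import select

logger = logging.getLogger(__name__)

#: grid spacing (degrees) of the landscape density
GRID_STEP_DEG = 1.0


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` minimises the
    (weighted) RMSD to ``reference``; ``R`` is always a proper rotation
    (det = +1, reflection branch corrected).

    Raises
    ------
    StructureError
        if the two point sets have different sizes.
    DegenerateBodyError
        if fewer than 3 points or the point set is (near-)collinear, which
        leaves the rotation underdetermined.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise StructureError(f"point-set size mismatch: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise DegenerateBodyError("need at least 3 paired 3-D points")
    if weights is None:
        w = np.full(len(P), 1.0 / len(P))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(P),) or np.any(w < 0) or w.sum() <= 0:
            raise StructureError("weights must be non-negative with positive sum")
        w = w / w.sum()

    p_cen = w @ P
    q_cen = w @ Q
    Pc = P - p_cen
    Qc = Q - q_cen

    H = (Pc * w[:, None]).T @ Qc  # covariance, mobile -> reference
    U, S, Vt = np.linalg.svd(H)
    # collinearity: rotation about the line is unobservable
    scale = max(S[0], 1e-30)
    if S[1] / scale < 1e-9:
        raise DegenerateBodyError("point set is collinear; rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q_cen - R @ p_cen
    residual = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.sum(w[:, None] * residual**2)))
    return R, t, rmsd


def _check_rotation(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise StructureError(f"rotation matrix must be 3x3, got {R.shape}")
    if np.abs(R.T @ R - np.eye(3)).max() > tol or abs(np.linalg.det(R) - 1.0) > tol:
        raise StructureError("matrix is not a proper orthonormal rotation")
    return R


@dataclass
class EulerPose:
    """(θ, ψ) orientation of one frame; θ about y in [−90, 90], ψ about x in
    (−180, 180].  ``gimbal_flag`` marks |θ| ≈ 90 where ψ is undefined."""

    theta: float
    psi: float
    frame: int = 0
    replicate: int = 0
    rmsd_nm: float = 0.0
    gimbal_flag: bool = False


def euler_from_rotation(R: np.ndarray, gimbal_tol: float = 1e-6) -> EulerPose:
    """Decompose a proper rotation, R = Rz(φ)·Ry(θ)·Rx(ψ), into (θ, ψ).

    θ = −asin(R₃₁) and ψ = atan2(R₃₂/cosθ, R₃₃/cosθ), valid when cosθ ≠ 0.
    Within ``gimbal_tol`` of cosθ = 0 the x- and z-rotations are inseparable:
    ψ is reported as 0 and the pose flagged.  φ is discarded by construction.
    """
    R = _check_rotation(R)
    r31 = float(np.clip(R[2, 0], -1.0, 1.0))
    theta = -np.arcsin(r31)
    cos_theta = np.cos(theta)
    if abs(cos_theta) < gimbal_tol:
        return EulerPose(theta=float(np.rad2deg(theta)), psi=0.0, gimbal_flag=True)
    psi = np.arctan2(R[2, 1] / cos_theta, R[2, 2] / cos_theta)
    return EulerPose(theta=float(np.rad2deg(theta)), psi=float(np.rad2deg(psi)))


@dataclass
class OrientationLandscape:
    poses: list[EulerPose]
    theta_grid: np.ndarray  # (n_theta,) degrees
    psi_grid: np.ndarray  # (n_psi,) degrees
    density: np.ndarray  # (n_theta, n_psi), integrates to 1 over deg²
    bandwidth: float  # KDE bandwidth factor actually used
    modes: list[dict] = field(default_factory=list)
    n_gimbal_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "poses": [vars(p) for p in self.poses],
            "theta_grid": self.theta_grid.tolist(),
            "psi_grid": self.psi_grid.tolist(),
            "density": self.density.tolist(),
            "bandwidth": self.bandwidth,
            "modes": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in m.items()}
                for m in self.modes
            ],
            "n_gimbal_excluded": self.n_gimbal_excluded,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrientationLandscape":
        return cls(
            poses=[EulerPose(**p) for p in d["poses"]],
            theta_grid=np.asarray(d["theta_grid"], dtype=float),
            psi_grid=np.asarray(d["psi_grid"], dtype=float),
            density=np.asarray(d["density"], dtype=float),
            bandwidth=float(d["bandwidth"]),
            modes=list(d["modes"]),
            n_gimbal_excluded=int(d.get("n_gimbal_excluded", 0)),
        )


def pose_series(
    trajectory: Trajectory,
    topology: Topology,
    reference_coords: np.ndarray,
    align_sel: str = "role protein",
    replicate: int = 0,
) -> list[EulerPose]:
    """Superpose the reference onto every frame and decompose the rotation.

    The pose of frame *f* is the rotation carrying the reference body into the
    frame's observed orientation (the inverse of the frame→reference
    alignment); decomposing this direction makes (θ, ψ) read as "how the body
    is oriented relative to the reference", with any rotation about z
    invisible.
    """
    idx = select(topology, align_sel)
    if len(idx) == 0:
        raise AnalysisError(f"alignment selection {align_sel!r} matched no atoms")
    ref = np.asarray(reference_coords, dtype=float)
    if ref.ndim != 2:
        raise StructureError("reference coordinates must be (n_atoms, 3)")
    if ref.shape[0] == topology.n_atoms:
        ref = ref[idx]
    elif ref.shape[0] != len(idx):
        raise StructureError(
            f"reference has {ref.shape[0]} atoms; expected {topology.n_atoms} "
            f"(full) or {len(idx)} (selection)"
        )
    poses = []
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f, idx]
        # align frame onto reference, then invert: pose = R_align.T
        R_align, _, rmsd = kabsch_superpose(frame, ref)
        pose = euler_from_rotation(R_align.T)
        pose.frame = f
        pose.replicate = replicate
        pose.rmsd_nm = rmsd
        poses.append(pose)
    return poses


def _kde_density(
    thetas: np.ndarray, psis: np.ndarray, bandwidth: float | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    theta_grid = np.arange(-90.0, 90.0 + GRID_STEP_DEG, GRID_STEP_DEG)
    psi_grid = np.arange(-180.0, 180.0 + GRID_STEP_DEG, GRID_STEP_DEG)
    try:
        kde = gaussian_kde(np.vstack([thetas, psis]), bw_method=bandwidth)
    except np.linalg.LinAlgError:
        # (near-)zero pose variance: all mass in the nearest grid cell
        dens = np.zeros((len(theta_grid), len(psi_grid)))
        i = int(np.argmin(np.abs(theta_grid - thetas.mean())))
        j = int(np.argmin(np.abs(psi_grid - psis.mean())))
        dens[i, j] = 1.0 / GRID_STEP_DEG**2
        return theta_grid, psi_grid, dens, 0.0
    TT, PP = np.meshgrid(theta_grid, psi_grid, indexing="ij")
    dens = kde(np.vstack([TT.ravel(), PP.ravel()])).reshape(TT.shape)
    # renormalise on the grid so cell-area-weighted density sums to one
    total = dens.sum() * GRID_STEP_DEG**2
    if total > 0:
        dens = dens / total
    return theta_grid, psi_grid, dens, float(kde.factor)


def _find_modes(
    theta_grid: np.ndarray,
    psi_grid: np.ndarray,
    density: np.ndarray,
    rel_threshold: float,
    min_separation: float,
) -> list[tuple[float, float, float]]:
    """8-neighbour local maxima at or above ``rel_threshold`` of the global
    maximum; ties broken by lower (θ, ψ).  Maxima closer than
    ``min_separation`` degrees to a denser one are suppressed — twin peaks
    within a kernel bandwidth are sampling noise, not distinct poses."""
    local_max = density == ndimage.maximum_filter(density, size=3, mode="nearest")
    strong = density >= rel_threshold * density.max()
    # collapse plateaus: keep lexicographically first cell of each connected plateau
    labels, n_lab = ndimage.label(local_max & strong)
    cand = []
    for lab in range(1, n_lab + 1):
        cells = np.argwhere(labels == lab)
        i, j = min(map(tuple, cells))
        cand.append((float(theta_grid[i]), float(psi_grid[j]), float(density[i, j])))
    cand.sort(key=lambda m: (-m[2], m[0], m[1]))
    modes: list[tuple[float, float, float]] = []
    for th, ps, de in cand:
        if all(pose_distance(th, ps, m[0], m[1]) >= min_separation for m in modes):
            modes.append((th, ps, de))
    return modes


def build_landscape(
    trajectory: Trajectory,
    topology: Topology,
    reference_coords: np.ndarray,
    align_sel: str = "role protein",
    bandwidth: float | None = None,
    mode_rel_threshold: float = 0.10,
    min_mode_separation_deg: float = 5.0,
    replicate: int = 0,
    poses: list[EulerPose] | None = None,
) -> OrientationLandscape:
    """Full orientation landscape: poses, KDE density grid and detected modes.

    ``poses`` may be supplied directly (e.g. pooled across replicates); then
    the trajectory arguments are ignored for pose computation.

    Each non-gimbal pose is also assigned to its nearest mode (wrapped
    Euclidean metric in (θ, ψ)); the member frame lists of the modes partition
    the frames.
    """
    if poses is None:
        poses = pose_series(trajectory, topology, reference_coords, align_sel, replicate)
    if not poses:
        raise AnalysisError("no poses to build a landscape from")
    usable = [p for p in poses if not p.gimbal_flag]
    n_gimbal = len(poses) - len(usable)
    if n_gimbal:
        logger.info("excluding %d gimbal-locked frame(s) from the density", n_gimbal)
    if len(usable) < 2:
        raise AnalysisError("fewer than 2 non-gimbal poses; density undefined")

    thetas = np.array([p.theta for p in usable])
    psis = np.array([p.psi for p in usable])
    theta_grid, psi_grid, dens, bw = _kde_density(thetas, psis, bandwidth)
    raw_modes = _find_modes(theta_grid, psi_grid, dens, mode_rel_threshold,
                            min_mode_separation_deg)

    modes: list[dict] = [
        {"theta": th, "psi": ps, "density": de, "members": []}
        for th, ps, de in raw_modes
    ]
    if modes:
        mode_th = np.array([m["theta"] for m in modes])
        mode_ps = np.array([m["psi"] for m in modes])
        for p in usable:
            d = pose_distance(p.theta, p.psi, mode_th, mode_ps)
            modes[int(np.argmin(d))]["members"].append(p.frame)
    return OrientationLandscape(
        poses=poses,
        theta_grid=theta_grid,
        psi_grid=psi_grid,
        density=dens,
        bandwidth=bw,
        modes=modes,
        n_gimbal_excluded=n_gimbal,
    )


def frames_near(
    landscape: OrientationLandscape, target: tuple[float, float], k: int
) -> list[int]:
    """The ``k`` frames whose pose is closest to ``target`` (θ, ψ) under the
    wrapped metric √(Δθ² + Δψ²_wrapped); if k exceeds the number of frames the
    full ordering is returned with a warning."""
    if not landscape.poses:
        raise AnalysisError("empty landscape")
    th0, ps0 = float(target[0]), wrap_angle(float(target[1]))
    poses = landscape.poses
    d = pose_distance(
        np.array([p.theta for p in poses]), np.array([p.psi for p in poses]), th0, ps0
    )
    if k > len(poses):
        logger.warning("requested k=%d frames but only %d available", k, len(poses))
        k = len(poses)
    order = np.argsort(d, kind="stable")[:k]
    return [poses[int(i)].frame for i in order]
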