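"""Flexibility analyses: tilt angles versus the membrane normal, per-residue
RMSF, and the spread of a multi-model ensemble.

The membrane normal is taken to be the +z axis of the box; the tilt of a
body-fixed vector (e.g. the N→C terminal axis of an ectodomain, or the
inositol-to-mannose vector of a GPI glycan) is its unsigned angle to +z in
[0°, 180°].  RMSF is computed about the trajectory-mean structure after
iterated least-squares superposition, which removes rigid-body motion so that
only internal fluctuation remains; the identical estimator applied to the
models of an NMR-style ensemble gives a directly comparable per-residue
spread profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, SelectionError, StructureError
from .model import Topology, Trajectory
from .orientation import kabsch_superpose
from .selection import select, select_one

#: convergence threshold (nm) and iteration cap of the mean-structure fit
SUPERPOSE_TOL_NM = 1e-6
SUPERPOSE_MAX_ITER = 10


@dataclass(frozen=True)
class AxisDefinition:
    """A labelled body axis given by two single-atom selections (tail → head)."""

    label: str
    tail: str
    head: str


def tilt_angle(v: np.ndarray) -> float:
    """Unsigned angle (degrees, [0, 180]) between a vector and the +z axis."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise AnalysisError("tilt angle of a zero vector is undefined")
    return float(np.rad2deg(np.arccos(np.clip(v[2] / n, -1.0, 1.0))))


def axis_angle_series(
    trajectory: Trajectory,
    topology: Topology,
    axis: AxisDefinition,
    replicate: int = 0,
) -> pd.DataFrame:
    """Per-frame tilt of ``head − tail`` versus +z.

    Returns a DataFrame with columns frame, angle_deg, replicate, label.
    """
    try:
        tail = select_one(topology, axis.tail)
        head = select_one(topology, axis.head)
    except SelectionError as exc:
        raise SelectionError(f"axis {axis.label!r}: {exc}") from exc
    vec = trajectory.coords[:, head] - trajectory.coords[:, tail]
    angles = np.rad2deg(
        np.arccos(np.clip(vec[:, 2] / np.linalg.norm(vec, axis=1), -1.0, 1.0))
    )
    return pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "angle_deg": angles,
            "replicate": replicate,
            "label": axis.label,
        }
    )


def _iterative_superpose(X: np.ndarray) -> np.ndarray:
    """Superpose every frame of (F, n, 3) onto the iterated mean structure."""
    X = X.copy()
    mean = X.mean(axis=0)
    for _ in range(SUPERPOSE_MAX_ITER):
        for f in range(X.shape[0]):
            R, t, _ = kabsch_superpose(X[f], mean)
            X[f] = X[f] @ R.T + t
        new_mean = X.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if shift < SUPERPOSE_TOL_NM:
            break
    return X


def rmsf(
    trajectory: Trajectory,
    topology: Topology,
    atom_sel: str = "role protein and name CA",
    superpose: bool = True,
    replicate: str | int = "pooled",
) -> pd.DataFrame:
    """Per-residue RMSF over the selected atoms (typically one Cα each).

    RMSF_i = √⟨‖r_i − ⟨r_i⟩‖²⟩ over frames, with frames first superposed onto
    the iterated mean structure when ``superpose`` (removing rigid-body
    motion).  Residues contributing several selected atoms report the mean of
    their atoms' values.
    """
    if trajectory.n_frames < 2:
        raise AnalysisError("RMSF undefined for fewer than 2 frames")
    idx = select(topology, atom_sel)
    if len(idx) == 0:
        raise SelectionError(f"selection {atom_sel!r} matched no atoms")
    X = trajectory.coords[:, idx]
    if superpose:
        X = _iterative_superpose(X)
    mean = X.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    rows: dict[tuple[str, int], list[float]] = {}
    for a, val in zip(idx, per_atom):
        atom = topology.atoms[int(a)]
        rows.setdefault((atom.chain, atom.residue_seq), []).append(float(val))
    return pd.DataFrame(
        [
            {"chain": chain, "residue_seq": seq, "rmsf_nm": float(np.mean(vals)),
             "replicate": replicate}
            for (chain, seq), vals in sorted(rows.items())
        ]
    )


def ensemble_spread(
    topology: Topology,
    ensemble: Trajectory,
    atom_sel: str = "role protein and name CA",
) -> pd.DataFrame:
    """Per-residue spread of a multi-model ensemble (models as frames).

    The models are superposed onto the ensemble mean and the per-residue RMSD
    about the mean is computed with the same estimator as :func:`rmsf`, so
    ensemble and trajectory profiles overlay directly.
    """
    if ensemble.n_frames < 2:
        raise StructureError("ensemble needs at least 2 models")
    out = rmsf(ensemble, topology, atom_sel=atom_sel, superpose=True, replicate="ensemble")
    return out.rename(columns={"rmsf_nm": "rmsd_nm"})
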