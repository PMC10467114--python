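"""Geometric hydrogen-bond detection and per-residue bond counting.

A donor–hydrogen–acceptor triplet is booked as a hydrogen bond when the
donor–acceptor distance is at most ``da_cutoff`` (default 3.0 Å) and the
D–H–A angle (vertex at the hydrogen) is at least ``dha_angle_min`` (default
150°).  Hydrogens are attached to donor heavy atoms by first-frame proximity
(≤ 1.2 Å) unless explicit assignments are given.  Donor/acceptor candidates
come either from selection expressions or from built-in atom-name tables for
protein residues and common phosphatidylcholine/cholesterol lipids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, SelectionError
from .model import Topology, Trajectory
from .selection import select

A_PER_NM = 10.0

#: maximum covalent D–H distance (Å) for first-frame hydrogen attachment
DH_ATTACH_A = 1.2

#: protein donor heavy atoms by (residue_name, atom_name); backbone N plus polar side chains
PROTEIN_DONOR_NAMES = {"N", "ND1", "ND2", "NE", "NE1", "NE2", "NH1", "NH2", "NZ",
                       "OG", "OG1", "OH", "SG"}
#: protein acceptors: backbone carbonyl plus side-chain O/N lone pairs
PROTEIN_ACCEPTOR_NAMES = {"O", "OXT", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH",
                          "ND1", "NE2"}
#: DOPC/POPC acceptors (phosphate + ester oxygens); PC lipids have no donors
LIPID_ACCEPTOR_NAMES = {"O11", "O12", "O13", "O14", "O21", "O22", "O31", "O32"}
#: cholesterol hydroxyl is both
CHOL_DONOR_NAMES = {"O3"}


@dataclass(frozen=True)
class HBondCriteria:
    """Donor–acceptor distance cutoff (Å) and minimum D–H–A angle (degrees)."""

    da_cutoff: float = 3.0
    dha_angle_min: float = 150.0

    def __post_init__(self):
        if self.da_cutoff <= 0:
            raise AnalysisError("da_cutoff must be positive")
        if not (0 <= self.dha_angle_min <= 180):
            raise AnalysisError("dha_angle_min must be within [0, 180] degrees")


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    distance_A: float
    angle_deg: float


def assign_hydrogens(
    topology: Topology,
    first_frame_nm: np.ndarray,
    donor_indices: np.ndarray,
) -> dict[int, list[int]]:
    """Attach hydrogens to donor heavy atoms by first-frame proximity.

    A hydrogen within 1.2 Å of a donor heavy atom is considered covalently
    bound to it (the nearest donor wins if several qualify).  Donors with no
    resolvable hydrogen are dropped — coarse-grain inputs simply yield no
    bonds rather than an error.
    """
    h_idx = np.flatnonzero(topology.role_masks["hydrogen"])
    mapping: dict[int, list[int]] = {int(d): [] for d in donor_indices}
    if len(h_idx) == 0 or len(donor_indices) == 0:
        return {d: hs for d, hs in mapping.items() if hs}
    dpos = first_frame_nm[donor_indices]
    hpos = first_frame_nm[h_idx]
    dist = np.linalg.norm(hpos[:, None, :] - dpos[None, :, :], axis=-1) * A_PER_NM
    for hi, row in zip(h_idx, dist):
        j = int(np.argmin(row))
        if row[j] <= DH_ATTACH_A:
            mapping[int(donor_indices[j])].append(int(hi))
    return {d: hs for d, hs in mapping.items() if hs}


def default_donor_acceptor_indices(
    topology: Topology, side: str
) -> tuple[np.ndarray, np.ndarray]:
    """Donor heavy atoms and acceptors for ``side`` in {"protein", "lipid"}
    from the built-in atom-name tables."""
    if side == "protein":
        mask = topology.role_masks["protein"]
        donors = np.flatnonzero(mask & np.isin(topology.names, sorted(PROTEIN_DONOR_NAMES)))
        acceptors = np.flatnonzero(mask & np.isin(topology.names, sorted(PROTEIN_ACCEPTOR_NAMES)))
    elif side == "lipid":
        mask = topology.role_masks["lipid"]
        donors = np.flatnonzero(mask & np.isin(topology.names, sorted(CHOL_DONOR_NAMES)))
        acceptors = np.flatnonzero(
            mask & np.isin(topology.names, sorted(LIPID_ACCEPTOR_NAMES | CHOL_DONOR_NAMES))
        )
    else:
        raise SelectionError(f"side must be 'protein' or 'lipid', got {side!r}")
    return donors, acceptors


def find_hbonds(
    frame_nm: np.ndarray,
    topology: Topology,
    donors_from: str | np.ndarray,
    acceptors_from: str | np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
    hydrogen_map: dict[int, list[int]] | None = None,
    frame_index: int = 0,
) -> list[HBondRecord]:
    """All (donor, hydrogen, acceptor) triplets of one frame satisfying the
    geometric criteria, donors drawn from one selection and acceptors from the
    other (run twice with swapped selections to capture both directions).

    ``donors_from``/``acceptors_from`` are selection expressions or index
    arrays of heavy atoms; ``hydrogen_map`` defaults to first-frame proximity
    assignment on this frame.
    """
    donors = (
        select(topology, donors_from) if isinstance(donors_from, str) else np.asarray(donors_from)
    )
    acceptors = (
        select(topology, acceptors_from)
        if isinstance(acceptors_from, str)
        else np.asarray(acceptors_from)
    )
    if hydrogen_map is None:
        hydrogen_map = assign_hydrogens(topology, frame_nm, donors)
    donors = np.array([d for d in donors if hydrogen_map.get(int(d))], dtype=int)
    records: list[HBondRecord] = []
    if len(donors) == 0 or len(acceptors) == 0:
        return records

    dpos = frame_nm[donors]
    apos = frame_nm[acceptors]
    dist_A = np.linalg.norm(dpos[:, None, :] - apos[None, :, :], axis=-1) * A_PER_NM
    cos_min = np.cos(np.deg2rad(criteria.dha_angle_min))
    for i, j in np.argwhere(dist_A <= criteria.da_cutoff):
        d_idx, a_idx = int(donors[i]), int(acceptors[j])
        if d_idx == a_idx:
            continue
        for h_idx in hydrogen_map[d_idx]:
            hv = frame_nm[h_idx]
            v1 = frame_nm[d_idx] - hv
            v2 = frame_nm[a_idx] - hv
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            cos_a = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
            angle = float(np.rad2deg(np.arccos(cos_a)))
            if angle >= criteria.dha_angle_min:
                records.append(
                    HBondRecord(
                        frame=frame_index,
                        donor=d_idx,
                        hydrogen=int(h_idx),
                        acceptor=a_idx,
                        distance_A=float(dist_A[i, j]),
                        angle_deg=angle,
                    )
                )
    return records


def find_hbonds_trajectory(
    trajectory: Trajectory,
    topology: Topology,
    donors_from: str | np.ndarray,
    acceptors_from: str | np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondRecord]:
    """Run :func:`find_hbonds` over every frame with hydrogens assigned once
    from the first frame."""
    donors = (
        select(topology, donors_from) if isinstance(donors_from, str) else np.asarray(donors_from)
    )
    hmap = assign_hydrogens(topology, trajectory.coords[0], donors)
    records: list[HBondRecord] = []
    for f in range(trajectory.n_frames):
        records.extend(
            find_hbonds(
                trajectory.coords[f],
                topology,
                donors,
                acceptors_from,
                criteria,
                hydrogen_map=hmap,
                frame_index=f,
            )
        )
    return records


def analyse_protein_lipid(
    trajectory: Trajectory,
    topology: Topology,
    protein_sel: str = "role protein",
    lipid_sel: str = "role lipid",
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondRecord]:
    """Both directions of protein–lipid hydrogen bonding over a trajectory:
    protein donors → lipid acceptors, and lipid donors (e.g. the cholesterol
    hydroxyl) → protein acceptors.  Donor/acceptor candidates come from the
    built-in atom-name tables restricted to the two selections."""
    prot = select(topology, protein_sel)
    lip = select(topology, lipid_sel)
    pd_, pa = default_donor_acceptor_indices(topology, "protein")
    ld, la = default_donor_acceptor_indices(topology, "lipid")
    records = find_hbonds_trajectory(
        trajectory, topology, np.intersect1d(pd_, prot), np.intersect1d(la, lip), criteria
    )
    records += find_hbonds_trajectory(
        trajectory, topology, np.intersect1d(ld, lip), np.intersect1d(pa, prot), criteria
    )
    return records


def per_residue_bond_average(
    records: list[HBondRecord],
    topology: Topology,
    n_frames_total: int,
    count: str = "donor",
) -> pd.DataFrame:
    """Mean number of hydrogen bonds per frame for each protein residue.

    ``count="donor"`` attributes a record to the residue of its donor atom
    only; ``count="both"`` also credits the acceptor's residue.  Replicates
    are pooled by passing their concatenated records with the summed frame
    count.
    """
    if n_frames_total <= 0:
        raise AnalysisError("n_frames_total must be positive")
    if count not in ("donor", "both"):
        raise AnalysisError(f"count must be 'donor' or 'both', got {count!r}")
    totals: dict[tuple[str, int], int] = {
        (chain, seq): 0
        for chain, seq, _ in topology.residues()
        if topology.role_masks["protein"][topology.residue_atoms(chain, seq)[0]]
    }
    for rec in records:
        for atom_idx in (rec.donor,) if count == "donor" else (rec.donor, rec.acceptor):
            atom = topology.atoms[atom_idx]
            key = (atom.chain, atom.residue_seq)
            if key in totals:
                totals[key] += 1
    rows = [
        {
            "chain": chain,
            "residue_seq": seq,
            "residue_name": topology.atoms[topology.residue_atoms(chain, seq)[0]].residue_name,
            "mean_bonds": n / n_frames_total,
        }
        for (chain, seq), n in totals.items()
    ]
    return pd.DataFrame(rows, columns=["chain", "residue_seq", "residue_name", "mean_bonds"])
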