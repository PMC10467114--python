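"""Internal data model: atoms, topology, trajectory.

Conventions enforced here and relied on everywhere else:

* lengths are **nanometres** internally (PDB ångströms are converted on read);
* frames and atom indices are **0-based**; ``residue_seq`` keeps the source
  file's (typically 1-based) numbering so residues can be named the way
  structural biologists name them (e.g. Y61);
* boxes are orthorhombic, stored as per-frame ``(lx, ly, lz)`` edge lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import StructureError

#: the role vocabulary an Atom may carry
ROLES = frozenset(
    {"protein", "lipid", "glycan_anchor", "hbond_donor", "hbond_acceptor", "hydrogen"}
)

#: standard amino-acid residue names used to assign the ``protein`` role
AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE PRO
       SER THR TRP TYR VAL""".split()
)

#: residue names the synthetic GPI glycan uses; real builds override via species_map
GLYCAN_RESNAMES = frozenset({"INO", "MAN", "GLU2", "ETA"})

#: default lipid residue-name -> species label mapping
DEFAULT_SPECIES_MAP = {
    "DOPC": "DOPC",
    "POPC": "POPC",
    "CHOL": "CHOL",
    "CHL1": "CHOL",
}


@dataclass(frozen=True)
class Atom:
    """One atom (or coarse-grain bead) of the system."""

    index: int
    name: str
    element: str
    residue_seq: int
    residue_name: str
    chain: str
    roles: frozenset = frozenset()

    def __post_init__(self):
        bad = set(self.roles) - ROLES
        if bad:
            raise StructureError(f"unknown atom roles {sorted(bad)} on atom {self.index}")
        if "hydrogen" in self.roles and self.element.upper() != "H":
            raise StructureError(
                f"atom {self.index} carries the hydrogen role but element is "
                f"{self.element!r}"
            )


class Topology:
    """Ordered atom list plus residue and species indexing.

    Parameters
    ----------
    atoms:
        Atoms ordered exactly as in the source file; ``atom.index`` must equal
        the position in this list.
    species_map:
        ``residue_name -> species label`` for lipid residues.  Merged over the
        defaults; every residue carrying the ``lipid`` role must be covered.
    """

    def __init__(self, atoms: Sequence[Atom], species_map: Mapping[str, str] | None = None):
        self.atoms: list[Atom] = list(atoms)
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise StructureError(f"atom index {a.index} at position {i}: not unique/ordered")
        self.species_map: dict[str, str] = dict(DEFAULT_SPECIES_MAP)
        if species_map:
            self.species_map.update(species_map)

        # vectorised columns for fast selection
        self.names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element.upper() for a in self.atoms])
        self.residue_seqs = np.array([a.residue_seq for a in self.atoms], dtype=int)
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.chains = np.array([a.chain for a in self.atoms])
        self.role_masks = {
            r: np.array([r in a.roles for a in self.atoms], dtype=bool) for r in ROLES
        }

        # (chain, residue_seq) -> atom index array, in file order
        self.residue_index: dict[tuple[str, int], np.ndarray] = {}
        order: list[tuple[str, int]] = []
        for a in self.atoms:
            key = (a.chain, a.residue_seq)
            if key not in self.residue_index:
                self.residue_index[key] = []
                order.append(key)
            self.residue_index[key].append(a.index)
        self.residue_index = {k: np.asarray(v, dtype=int) for k, v in self.residue_index.items()}
        self._residue_order = order

        missing = {
            a.residue_name
            for a in self.atoms
            if "lipid" in a.roles and a.residue_name not in self.species_map
        }
        if missing:
            raise StructureError(f"species_map does not cover lipid residue names {sorted(missing)}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self) -> Iterable[tuple[str, int, str]]:
        """Yield ``(chain, residue_seq, residue_name)`` in first-appearance order."""
        for chain, seq in self._residue_order:
            first = self.residue_index[(chain, seq)][0]
            yield chain, seq, self.atoms[first].residue_name

    def residue_atoms(self, chain: str, residue_seq: int) -> np.ndarray:
        try:
            return self.residue_index[(chain, residue_seq)]
        except KeyError:
            raise StructureError(f"no residue {residue_seq} in chain {chain!r}")

    def species_of(self, residue_name: str) -> str | None:
        return self.species_map.get(residue_name)

    def lipid_molecules(self, species: str) -> list[tuple[str, int]]:
        """All ``(chain, residue_seq)`` lipid molecules of a given species label."""
        out = []
        for chain, seq, rname in self.residues():
            if self.species_map.get(rname) == species:
                out.append((chain, seq))
        return out


@dataclass
class Trajectory:
    """Per-frame coordinates in nm, with optional box lengths and time stamps."""

    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    box: np.ndarray | None = None  # (n_frames, 3) nm, orthorhombic edges
    time_ps: np.ndarray | None = None  # (n_frames,)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise StructureError(f"box must be ({self.n_frames}, 3), got {self.box.shape}")
            if np.any(self.box <= 0):
                raise StructureError("box lengths must be positive")
        if self.time_ps is not None:
            self.time_ps = np.asarray(self.time_ps, dtype=float)
            if self.time_ps.shape != (self.n_frames,):
                raise StructureError("time_ps length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def check_consistent(topology: Topology, trajectory: Trajectory) -> None:
    """Raise unless the trajectory's atom dimension matches the topology."""
    if trajectory.n_atoms != topology.n_atoms:
        raise StructureError(
            f"trajectory has {trajectory.n_atoms} atoms per frame, topology has "
            f"{topology.n_atoms}"
        )
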