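"""Structure and trajectory I/O.

Multi-model PDB is the mandatory format: each ``MODEL`` becomes one frame,
``CRYST1`` populates the (orthorhombic) box.  Coordinates are converted from
ångström to nanometre on read and back on write.

The fixed-column reader/writer here handles the narrow record set this
package needs (ATOM/HETATM/MODEL/ENDMDL/CRYST1) and deliberately accepts
four-character residue names in columns 18–21 — the CHARMM/VMD convention
used for lipids such as DOPC and CHL1, which strict three-character PDB
implementations mangle.  Other trajectory formats can be plugged in behind
the same ``(Topology, Trajectory)`` contract.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .errors import ParseError, StructureError
from .model import (
    AMINO_ACIDS,
    DEFAULT_SPECIES_MAP,
    GLYCAN_RESNAMES,
    Atom,
    Topology,
    Trajectory,
    check_consistent,
)

A_PER_NM = 10.0

_ELEMENT_GUESS = re.compile(r"[A-Za-z]")


def _guess_element(atom_name: str) -> str:
    """First alphabetic character of the atom name; good enough for fixtures
    and CG beads (which are treated as atoms)."""
    m = _ELEMENT_GUESS.search(atom_name)
    return m.group(0).upper() if m else "X"


def assign_roles(residue_name: str, element: str, species_map: dict[str, str]) -> frozenset:
    roles = set()
    if residue_name in AMINO_ACIDS:
        roles.add("protein")
    if residue_name in species_map:
        roles.add("lipid")
    if residue_name in GLYCAN_RESNAMES:
        roles.add("glycan_anchor")
    if element.upper() == "H":
        roles.add("hydrogen")
    return frozenset(roles)


def _parse_atom_line(line: str, lineno: int, path) -> tuple:
    try:
        name = line[12:16].strip()
        altloc = line[16].strip() if len(line) > 16 else ""
        resname = line[17:21].strip()
        chain = line[21].strip() if len(line) > 21 else ""
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        raise ParseError(
            f"{path}: malformed {line[:6].strip()} record at line {lineno}: "
            f"{line.rstrip()!r}"
        )
    element = line[76:78].strip() if len(line) >= 78 else ""
    return name, altloc, resname, chain, resseq, (x, y, z), element


def _parse_cryst1(line: str, lineno: int, path) -> np.ndarray | None:
    try:
        a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
        alpha, beta, gamma = (float(line[33:40]), float(line[40:47]), float(line[47:54]))
    except (ValueError, IndexError):
        raise ParseError(f"{path}: malformed CRYST1 record at line {lineno}")
    if a <= 0 or b <= 0 or c <= 0:
        return None  # placeholder CRYST1 (e.g. 1 1 1 or zeros): no box
    if max(abs(alpha - 90), abs(beta - 90), abs(gamma - 90)) > 1e-3:
        raise StructureError(f"{path}: only orthorhombic boxes are supported")
    return np.array([a, b, c]) / A_PER_NM


def read_structure(
    path, format: str = "pdb", species_map: dict[str, str] | None = None
) -> tuple[Topology, Trajectory]:
    """Read a (multi-model) PDB file into the internal data model.

    Parameters
    ----------
    path:
        PDB file; each MODEL becomes one trajectory frame (frames ordered by
        MODEL number; a single-model file yields one frame).
    species_map:
        Extra ``residue_name -> species`` entries for lipid residues beyond
        the built-in defaults (DOPC, POPC, CHOL/CHL1).

    Returns
    -------
    (Topology, Trajectory) with coordinates in nm; CRYST1, when present and
    non-degenerate, becomes the per-frame orthorhombic box.
    """
    if format != "pdb":
        raise ParseError(f"unsupported structure format {format!r}; only 'pdb' is built in")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")

    smap = dict(DEFAULT_SPECIES_MAP)
    if species_map:
        smap.update(species_map)

    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    meta: list[tuple] = []  # (name, resname, chain, resseq, element) of frame 0
    box_nm: np.ndarray | None = None
    first_frame_done = False
    saw_model = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                name, altloc, resname, chain, resseq, xyz, element = _parse_atom_line(
                    line, lineno, path)
                if altloc not in ("", "A"):
                    continue  # keep the first alternate location only
                current.append(xyz)
                if not first_frame_done:
                    meta.append((name, resname, chain, resseq, element))
            elif rec == "MODEL":
                saw_model = True
                if current:
                    frames.append(current)
                    first_frame_done = True
                    current = []
            elif rec == "ENDMDL":
                frames.append(current)
                first_frame_done = True
                current = []
            elif rec == "CRYST1":
                parsed = _parse_cryst1(line, lineno, path)
                if parsed is not None:
                    box_nm = parsed
    if current:
        frames.append(current)
    if not frames or not frames[0]:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    counts = {len(f) for f in frames}
    if len(counts) > 1:
        raise StructureError(
            f"{path}: inconsistent atom count across models: {sorted(counts)}"
        )
    del saw_model  # single-model and multi-model files converge here

    atoms = []
    for i, (name, resname, chain, resseq, element) in enumerate(meta):
        el = element if element else _guess_element(name)
        atoms.append(
            Atom(index=i, name=name, element=el, residue_seq=resseq,
                 residue_name=resname, chain=chain,
                 roles=assign_roles(resname, el, smap))
        )
    topo = Topology(atoms, species_map=species_map)
    coords_nm = np.asarray(frames, dtype=float) / A_PER_NM
    box = np.tile(box_nm, (len(frames), 1)) if box_nm is not None else None
    traj = Trajectory(coords=coords_nm, box=box)
    check_consistent(topo, traj)
    return topo, traj


def _format_atom_line(serial: int, atom: Atom, xyz_A: np.ndarray) -> str:
    record = "ATOM" if "protein" in atom.roles else "HETATM"
    # short atom names start in column 14 by convention
    name = atom.name if len(atom.name) >= 4 else f" {atom.name}"
    return (
        f"{record:<6}{serial % 100000:>5} {name:<4}{'':1}{atom.residue_name:<4}"
        f"{atom.chain[:1] or 'A':1}{atom.residue_seq % 10000:>4}{'':1}   "
        f"{xyz_A[0]:8.3f}{xyz_A[1]:8.3f}{xyz_A[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {atom.element[:2]:>2}"
    )


def write_structure(path, topology: Topology, trajectory: Trajectory) -> None:
    """Write a (multi-model) PDB file; inverse of :func:`read_structure` to
    PDB coordinate precision (0.001 Å)."""
    check_consistent(topology, trajectory)
    multi = trajectory.n_frames > 1
    lines: list[str] = []
    if trajectory.box is not None:
        a, b, c = trajectory.box[0] * A_PER_NM
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    for f in range(trajectory.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:>4}")
        frame_A = trajectory.coords[f] * A_PER_NM
        if np.abs(frame_A).max() >= 10000:
            raise StructureError(
                "coordinates exceed the PDB fixed-column range (|x| < 1000 nm)"
            )
        for atom in topology.atoms:
            lines.append(_format_atom_line(atom.index + 1, atom, frame_A[atom.index]))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
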