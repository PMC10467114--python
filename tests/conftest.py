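import numpy as np
import pytest

from gpitraj.model import Atom, Topology, Trajectory


def make_topology(spec):
    """Build a Topology from a compact spec: list of
    (name, element, residue_seq, residue_name, chain, roles)."""
    atoms = [
        Atom(index=i, name=n, element=e, residue_seq=rs, residue_name=rn,
             chain=c, roles=frozenset(roles))
        for i, (n, e, rs, rn, c, roles) in enumerate(spec)
    ]
    return Topology(atoms)


@pytest.fixture
def mini_protein():
    """Three-residue peptide with backbone N/CA/C/O and one hydrogen."""
    spec = []
    for seq in (1, 2, 3):
        spec += [
            ("N", "N", seq, "ALA", "A", {"protein"}),
            ("H", "H", seq, "ALA", "A", {"protein", "hydrogen"}),
            ("CA", "C", seq, "ALA", "A", {"protein"}),
            ("C", "C", seq, "ALA", "A", {"protein"}),
            ("O", "O", seq, "ALA", "A", {"protein"}),
        ]
    return make_topology(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20230430)


def single_atom_residues(n, chain="A", resname="ALA", roles=("protein",), name="CA",
                         element="C", start_seq=1):
    return [
        (name, element, start_seq + i, resname, chain, set(roles)) for i in range(n)
    ]


def trajectory_from(coords, box=None):
    return Trajectory(coords=np.asarray(coords, dtype=float), box=box)
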