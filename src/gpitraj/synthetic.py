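"""Synthetic trajectories with analytic ground truth.

These generators emulate the *statistical* structure of membrane-protein
simulation output so that every analysis stage can be validated without any
real trajectory:

* a rigid pseudo-Cα body whose orientation samples a mixture of preferred
  (θ, ψ) poses with the z-rotation φ uniform — the orientation-landscape
  analogue of a GPI-tethered ectodomain exploring poses over a membrane;
* per-pair residue–lipid minimum-distance series driven by two-state
  (bound/unbound) Markov kinetics, whose stationary occupancy
  p_on/(p_on+p_off) and geometric mean dwell 1/p_off are known in closed
  form;
* donor–hydrogen–acceptor triplets constructed at exactly requested
  distance/angle geometry;
* per-residue isotropic Gaussian positional jitter of known amplitude σ,
  for which the RMSF is √3·σ exactly.

Every generator is a pure function of its spec (seed included): identical
spec ⇒ bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactCriteria
from .errors import DegenerateBodyError, SpecError
from .geometry import compose_zyx
from .model import Atom, Topology, Trajectory

NM_PER_A = 0.1

#: default covalent D–H distance used when realising H-bond triplets (Å)
DH_BOND_A = 1.0


def make_ca_body(
    n_residues: int, seed: int = 0, spread_nm: float = 1.0, arrangement: str = "gaussian"
) -> tuple[Topology, np.ndarray]:
    """A compact pseudo-Cα body: one CA atom per residue.

    ``arrangement="gaussian"`` draws coordinates once from a centred isotropic
    Gaussian of the given spread; ``"shell"`` places them on a sphere of that
    radius, which spreads the rigid-body degrees of freedom absorbed by
    superposition evenly over the residues (useful for fluctuation fixtures,
    where no residue should be biased more than another).  Used both as a
    rigid reference body and as the base structure for jitter fixtures."""
    if n_residues < 1:
        raise SpecError("need at least one residue")
    rng = np.random.default_rng(seed)
    coords = rng.normal(0.0, spread_nm, size=(n_residues, 3))
    if arrangement == "shell":
        coords *= spread_nm / np.linalg.norm(coords, axis=1, keepdims=True)
    elif arrangement != "gaussian":
        raise SpecError(f"unknown arrangement {arrangement!r}")
    coords -= coords.mean(axis=0)
    atoms = [
        Atom(index=i, name="CA", element="C", residue_seq=i + 1, residue_name="ALA",
             chain="A", roles=frozenset({"protein"}))
        for i in range(n_residues)
    ]
    return Topology(atoms), coords


def _check_rigid_body(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 4:
        raise DegenerateBodyError("reference body needs at least 4 points in 3-D")
    centred = coords - coords.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[2] / max(s[0], 1e-30) < 1e-9:
        raise DegenerateBodyError("reference body is coplanar; Kabsch would be underdetermined")
    return coords


@dataclass(frozen=True)
class OrientationMixtureSpec:
    """Mixture of preferred poses: components are
    (mean_theta_deg, mean_psi_deg, stdev_deg, weight)."""

    components: tuple
    n_frames: int
    seed: int
    reference_coords: np.ndarray | None = None

    def __post_init__(self):
        if self.n_frames < 1:
            raise SpecError("n_frames must be positive")
        if not self.components:
            raise SpecError("need at least one mixture component")
        total = 0.0
        for mt, mp, sd, w in self.components:
            if not (-90.0 <= mt <= 90.0):
                raise SpecError(f"mean_theta {mt} outside [-90, 90]")
            if not (-180.0 < mp <= 180.0):
                raise SpecError(f"mean_psi {mp} outside (-180, 180]")
            if sd <= 0:
                raise SpecError("stdev must be positive")
            total += w
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"component weights sum to {total}, expected 1")


def make_orientation_trajectory(
    spec: OrientationMixtureSpec,
) -> tuple[Topology, Trajectory, pd.DataFrame]:
    """Rigid-body trajectory sampling the pose mixture.

    Frame *f* applies Rz(φ_f)·Ry(θ_f)·Rx(ψ_f) about the body centroid, with
    φ uniform on (−180, 180] and (θ, ψ) Gaussian around the drawn component's
    means (clipped to the valid ranges).  Truth columns: frame, component,
    theta_deg, psi_deg, phi_deg.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.reference_coords is None:
        topo, ref = make_ca_body(16, seed=spec.seed)
    else:
        ref = _check_rigid_body(spec.reference_coords)
        topo, _ = make_ca_body(ref.shape[0], seed=spec.seed)
    ref = _check_rigid_body(ref)
    centroid = ref.mean(axis=0)

    weights = np.array([c[3] for c in spec.components], dtype=float)
    comp_ids = rng.choice(len(spec.components), size=spec.n_frames, p=weights / weights.sum())
    thetas = np.empty(spec.n_frames)
    psis = np.empty(spec.n_frames)
    for f, c in enumerate(comp_ids):
        mt, mp, sd, _ = spec.components[c]
        thetas[f] = np.clip(rng.normal(mt, sd), -90.0, 90.0)
        psi = np.clip(rng.normal(mp, sd), -180.0, 180.0)
        psis[f] = 180.0 if psi == -180.0 else psi
    phis = rng.uniform(-180.0, 180.0, size=spec.n_frames)

    coords = np.empty((spec.n_frames, ref.shape[0], 3))
    body = ref - centroid
    for f in range(spec.n_frames):
        R = compose_zyx(phis[f], thetas[f], psis[f])
        coords[f] = body @ R.T + centroid
    truth = pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "component": comp_ids,
            "theta_deg": thetas,
            "psi_deg": psis,
            "phi_deg": phis,
        }
    )
    return topo, Trajectory(coords=coords), truth


@dataclass(frozen=True)
class ContactKineticsSpec:
    """Two-state Markov binding kinetics for residue–lipid distance series.

    Bound frames draw their distance uniformly from ``bound_distance_range``
    (entirely below the lower cutoff in force), unbound frames from
    ``unbound_distance_range`` (entirely above the upper cutoff), so the
    dual-cutoff booking is unambiguous by construction.
    """

    p_on: float
    p_off: float
    n_frames: int
    n_pairs: int
    seed: int
    bound_distance_range: tuple = (0.30, 0.50)
    unbound_distance_range: tuple = (1.10, 2.00)
    criteria: ContactCriteria = field(default_factory=ContactCriteria)

    def __post_init__(self):
        if not (0.0 <= self.p_on <= 1.0 and 0.0 <= self.p_off <= 1.0):
            raise SpecError("p_on and p_off must lie in [0, 1]")
        if self.n_frames < 1 or self.n_pairs < 1:
            raise SpecError("n_frames and n_pairs must be positive")
        blo, bhi = self.bound_distance_range
        ulo, uhi = self.unbound_distance_range
        if not (0 < blo <= bhi and 0 < ulo <= uhi):
            raise SpecError("distance ranges must be positive and ordered")
        if bhi >= self.criteria.lower_cutoff:
            raise SpecError(
                "bound distance range must lie entirely below the lower cutoff "
                f"({self.criteria.lower_cutoff} nm); booking would be ambiguous"
            )
        if ulo <= self.criteria.upper_cutoff:
            raise SpecError(
                "unbound distance range must lie entirely above the upper cutoff "
                f"({self.criteria.upper_cutoff} nm); booking would be ambiguous"
            )


def make_contact_series(spec: ContactKineticsSpec) -> tuple[np.ndarray, np.ndarray]:
    """Distance series (n_pairs, n_frames) nm plus the true bound/unbound
    state sequence (same shape, boolean).

    The chain starts in its stationary distribution (π_bound =
    p_on/(p_on+p_off); unbound when both rates are zero), so empirical
    occupancy is unbiased at any length.
    """
    rng = np.random.default_rng(spec.seed)
    P, F = spec.n_pairs, spec.n_frames
    states = np.empty((P, F), dtype=bool)
    rate_sum = spec.p_on + spec.p_off
    pi_bound = spec.p_on / rate_sum if rate_sum > 0 else 0.0
    state = rng.random(P) < pi_bound
    for f in range(F):
        states[:, f] = state
        u = rng.random(P)
        go_on = ~state & (u < spec.p_on)
        go_off = state & (u < spec.p_off)
        state = (state | go_on) & ~go_off
    blo, bhi = spec.bound_distance_range
    ulo, uhi = spec.unbound_distance_range
    distances = np.where(
        states,
        rng.uniform(blo, bhi, size=(P, F)),
        rng.uniform(ulo, uhi, size=(P, F)),
    )
    return distances, states


def make_contact_trajectory(
    spec: ContactKineticsSpec,
) -> tuple[Topology, Trajectory, np.ndarray]:
    """Embed the distance series as a real system: each pair becomes one
    single-atom protein residue and one single-bead DOPC molecule sitting at
    the generated distance along x, with pairs spaced 50 nm apart on a grid so
    no cross-pair contacts exist.  Returns (topology, trajectory, true
    states)."""
    distances, states = make_contact_series(spec)
    P, F = distances.shape
    atoms = []
    for p in range(P):
        atoms.append(
            Atom(index=2 * p, name="CA", element="C", residue_seq=p + 1,
                 residue_name="ALA", chain="A", roles=frozenset({"protein"}))
        )
        atoms.append(
            Atom(index=2 * p + 1, name="PO4", element="P", residue_seq=p + 1,
                 residue_name="DOPC", chain="L", roles=frozenset({"lipid"}))
        )
    topo = Topology(atoms)
    coords = np.zeros((F, 2 * P, 3))
    offsets = np.arange(P) * 50.0
    coords[:, 0::2, 1] = offsets[None, :]
    coords[:, 1::2, 1] = offsets[None, :]
    coords[:, 1::2, 0] = distances.T
    return topo, Trajectory(coords=coords), states


@dataclass(frozen=True)
class HBondFixtureSpec:
    """Triplets of (donor–acceptor distance Å, D–H–A angle deg, expected_bond)."""

    triplets: tuple
    seed: int = 0

    def __post_init__(self):
        for d, a, _ in self.triplets:
            if d <= 0:
                raise SpecError(f"D–A distance must be positive, got {d}")
            if not (0.0 <= a <= 180.0):
                raise SpecError(f"D–H–A angle must be in [0, 180], got {a}")


def make_hbond_frames(spec: HBondFixtureSpec) -> tuple[Topology, Trajectory]:
    """One frame realising every triplet at exactly its requested geometry.

    Each triplet becomes donor N (origin), hydrogen H at 1.0 Å along x, and
    acceptor O placed so that |D−A| and the D–H–A angle (vertex at H) match
    the spec; triplets are separated by 5 nm along z so they cannot interact.
    Raises on geometrically unrealisable triplets (e.g. D–A shorter than the
    D–H bond at a straight angle).
    """
    h = DH_BOND_A
    atoms = []
    pos = []
    for i, (d, angle, _) in enumerate(spec.triplets):
        alpha = np.deg2rad(angle)
        disc = d**2 - (h * np.sin(alpha)) ** 2
        r = h * np.cos(alpha) + np.sqrt(disc) if disc >= 0 else -1.0
        if r <= 0:
            raise SpecError(
                f"triplet {i}: D–A {d} Å with D–H–A {angle}° is geometrically "
                f"unrealisable at a {h} Å D–H bond"
            )
        z = 50.0 * i  # Å
        donor = np.array([0.0, 0.0, z])
        hydrogen = np.array([h, 0.0, z])
        # direction from H making the requested angle with H->D = (-1, 0, 0)
        acceptor = hydrogen + r * np.array([-np.cos(alpha), np.sin(alpha), 0.0])
        base = 3 * i
        atoms.extend(
            [
                Atom(index=base, name="N", element="N", residue_seq=i + 1,
                     residue_name="DNR", chain="D", roles=frozenset()),
                Atom(index=base + 1, name="H", element="H", residue_seq=i + 1,
                     residue_name="DNR", chain="D", roles=frozenset({"hydrogen"})),
                Atom(index=base + 2, name="O", element="O", residue_seq=i + 1,
                     residue_name="ACC", chain="E", roles=frozenset()),
            ]
        )
        pos.extend([donor, hydrogen, acceptor])
    topo = Topology(atoms)
    coords = np.asarray(pos)[None, :, :] * NM_PER_A  # Å -> nm, single frame
    return topo, Trajectory(coords=coords)


def make_jitter_trajectory(
    topology: Topology,
    base_coords: np.ndarray,
    sigma_nm,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Base structure plus per-residue isotropic Gaussian noise (stdev
    ``sigma_nm`` per axis, one value per residue in topology order); no
    rigid-body drift is added, so the exact per-residue RMSF is √3·σ."""
    base = np.asarray(base_coords, dtype=float)
    if base.shape != (topology.n_atoms, 3):
        raise SpecError(f"base coords shape {base.shape} != ({topology.n_atoms}, 3)")
    residues = list(topology.residues())
    sigma = np.asarray(sigma_nm, dtype=float)
    if sigma.ndim == 0:
        sigma = np.full(len(residues), float(sigma))
    if sigma.shape != (len(residues),):
        raise SpecError(f"need one sigma per residue ({len(residues)}), got {sigma.shape}")
    if np.any(sigma < 0):
        raise SpecError("sigma must be non-negative")
    per_atom_sigma = np.empty(topology.n_atoms)
    for s, (chain, seq, _) in zip(sigma, residues):
        per_atom_sigma[topology.residue_atoms(chain, seq)] = s
    if n_frames < 1:
        raise SpecError("n_frames must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=(n_frames, topology.n_atoms, 3)) * per_atom_sigma[None, :, None]
    return Trajectory(coords=base[None, :, :] + noise)
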