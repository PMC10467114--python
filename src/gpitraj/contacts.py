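"""Residue–lipid contact analysis with a dual-cutoff (hysteresis) definition.

A contact between a residue and a lipid molecule *starts* at the first frame
where their minimum atom–atom distance drops below the lower cutoff
(default 0.55 nm) and *persists* while the distance stays below the upper
cutoff (default 1.0 nm); it ends at the first frame at or above the upper
cutoff.  The band between the two cutoffs suppresses boundary flicker, so a
lipid rattling around a binding site is booked as one long event rather than
many short ones.  Per residue and lipid species this yields

* occupancy — % of frames in contact with ≥1 molecule of the species, and
* residence time — by default the mean contact-event duration (an optional
  estimator fits exponentials to the event-survival curve instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import AnalysisError, SelectionError
from .geometry import min_image_displacement
from .model import Topology, Trajectory

DEFAULT_LOWER_NM = 0.55
DEFAULT_UPPER_NM = 1.0


@dataclass(frozen=True)
class ContactCriteria:
    """Dual distance cutoffs in nm; lower < upper."""

    lower_cutoff: float = DEFAULT_LOWER_NM
    upper_cutoff: float = DEFAULT_UPPER_NM

    def __post_init__(self):
        # equality is allowed: it degenerates to simple single-threshold booking
        if not (0 < self.lower_cutoff <= self.upper_cutoff):
            raise AnalysisError(
                f"need 0 < lower <= upper, got ({self.lower_cutoff}, {self.upper_cutoff})"
            )


@dataclass(frozen=True)
class ContactEvent:
    """One residue–lipid contact over the half-open frame window [start, end)."""

    residue: tuple[str, int]  # (chain, residue_seq)
    lipid: tuple[str, int]
    start_frame: int
    end_frame: int

    @property
    def duration(self) -> int:
        return self.end_frame - self.start_frame


def min_distance_series(
    trajectory: Trajectory,
    topology: Topology,
    residue: tuple[str, int],
    lipid: tuple[str, int],
) -> np.ndarray:
    """Per-frame minimum atom–atom distance (nm) between a residue and a lipid
    molecule, with per-axis minimum-image wrapping when a box is present."""
    ri = topology.residue_atoms(*residue)
    li = topology.residue_atoms(*lipid)
    if len(ri) == 0 or len(li) == 0:
        raise SelectionError(f"empty selection for residue {residue} or lipid {lipid}")
    a = trajectory.coords[:, ri]  # (F, na, 3)
    b = trajectory.coords[:, li]  # (F, nb, 3)
    delta = a[:, :, None, :] - b[:, None, :, :]  # (F, na, nb, 3)
    if trajectory.box is not None:
        delta = delta - trajectory.box[:, None, None, :] * np.round(
            delta / trajectory.box[:, None, None, :]
        )
    d = np.sqrt(np.sum(delta**2, axis=-1))
    return d.min(axis=(1, 2))


def min_distance_points(a: np.ndarray, b: np.ndarray, box=None) -> float:
    """Minimum pairwise distance between two coordinate sets of one frame."""
    delta = a[:, None, :] - b[None, :, :]
    delta = min_image_displacement(delta, box)
    return float(np.sqrt(np.sum(delta**2, axis=-1)).min())


def book_events(
    distances: np.ndarray,
    criteria: ContactCriteria = ContactCriteria(),
    residue: tuple[str, int] = ("", 0),
    lipid: tuple[str, int] = ("", 0),
) -> list[ContactEvent]:
    """Book contact events from one distance series under the dual-cutoff rule.

    A contact starts at the first frame with d < lower while unbound, persists
    while d < upper, and ends at the first frame with d ≥ upper; an event
    still open at the trajectory end is closed at n_frames (the truncated
    duration is counted as-is, no censoring correction).
    """
    d = np.asarray(distances, dtype=float)
    if d.size and not np.all(np.isfinite(d)):
        raise AnalysisError("distance series contains non-finite values")
    events: list[ContactEvent] = []
    start = None
    for f, x in enumerate(d):
        if start is None:
            if x < criteria.lower_cutoff:
                start = f
        else:
            if x >= criteria.upper_cutoff:
                events.append(ContactEvent(residue, lipid, start, f))
                start = None
                if x < criteria.lower_cutoff:  # unreachable when lower < upper
                    start = f
    if start is not None:
        events.append(ContactEvent(residue, lipid, start, len(d)))
    return events


def _survival_curve(durations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalised event-survival curve S(t) = fraction of events lasting ≥ t."""
    t = np.arange(0, durations.max() + 1)
    s = np.array([(durations >= ti).mean() for ti in t])
    return t, s


def survival_residence_time(durations: np.ndarray, double: bool = True) -> float:
    """Residence time from a least-squares exponential fit to the survival
    curve.  Single exponential: S = exp(−t/τ) → τ.  Double exponential:
    S = A·exp(−t/τ₁) + (1−A)·exp(−t/τ₂) → mixture mean A·τ₁ + (1−A)·τ₂.
    Falls back to the single-exponential (then to the empirical mean) when
    the fit cannot converge."""
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        return 0.0
    t, s = _survival_curve(durations)
    mean = durations.mean()
    if double and t.size >= 4:
        try:
            popt, _ = curve_fit(
                lambda t, a, tau1, tau2: a * np.exp(-t / tau1) + (1 - a) * np.exp(-t / tau2),
                t,
                s,
                p0=[0.5, max(mean, 1.0), max(mean / 5.0, 0.5)],
                bounds=([0.0, 1e-6, 1e-6], [1.0, np.inf, np.inf]),
                maxfev=5000,
            )
            a, tau1, tau2 = popt
            return float(a * tau1 + (1 - a) * tau2)
        except RuntimeError:
            pass
    if t.size >= 2:
        try:
            popt, _ = curve_fit(
                lambda t, tau: np.exp(-t / tau), t, s, p0=[max(mean, 1.0)], maxfev=5000
            )
            return float(popt[0])
        except RuntimeError:
            pass
    return float(mean)


@dataclass
class ContactStats:
    residue: tuple[str, int]
    species: str
    occupancy_pct: float
    residence_frames: float
    n_events: int
    residence_ns: float | None = None


def contact_stats(
    events_per_pair: dict[tuple[tuple[str, int], tuple[str, int]], list[ContactEvent]],
    n_frames: int,
    topology: Topology,
    estimator: str = "mean",
    frame_dt_ns: float | None = None,
) -> list[ContactStats]:
    """Aggregate booked events into per-(residue, species) statistics.

    occupancy = 100 × |union of in-contact frames over the species'
    molecules| / n_frames; residence time pools event durations over the
    species' molecules (``estimator``: "mean" for mean event duration,
    "survival-exp" for the exponential-survival fit).
    """
    if n_frames <= 0:
        raise AnalysisError("empty trajectory: n_frames must be positive")
    if estimator not in ("mean", "survival-exp"):
        raise AnalysisError(f"unknown residence estimator {estimator!r}")
    grouped: dict[tuple[tuple[str, int], str], list[ContactEvent]] = {}
    for (residue, lipid), events in events_per_pair.items():
        lip_atoms = topology.residue_atoms(*lipid)
        species = topology.species_of(topology.atoms[lip_atoms[0]].residue_name)
        if species is None:
            species = topology.atoms[lip_atoms[0]].residue_name
        grouped.setdefault((residue, species), []).extend(events)

    out = []
    for (residue, species), events in sorted(grouped.items()):
        mask = np.zeros(n_frames, dtype=bool)
        for ev in events:
            mask[ev.start_frame : ev.end_frame] = True
        occ = 100.0 * mask.sum() / n_frames
        durations = np.array([ev.duration for ev in events], dtype=float)
        if durations.size == 0:
            res = 0.0
        elif estimator == "mean":
            res = float(durations.mean())
        else:
            res = survival_residence_time(durations)
        out.append(
            ContactStats(
                residue=residue,
                species=species,
                occupancy_pct=occ,
                residence_frames=res,
                n_events=len(events),
                residence_ns=res * frame_dt_ns if frame_dt_ns is not None else None,
            )
        )
    return out


def analyse_contacts(
    trajectory: Trajectory,
    topology: Topology,
    species: list[str],
    criteria: ContactCriteria = ContactCriteria(),
    residue_sel_role: str = "protein",
    estimator: str = "mean",
) -> list[ContactStats]:
    """End-to-end contact analysis: distance series → events → statistics for
    every protein residue against every lipid molecule of the given species."""
    residues = [
        (chain, seq)
        for chain, seq, rname in topology.residues()
        if residue_sel_role in topology.atoms[topology.residue_atoms(chain, seq)[0]].roles
    ]
    lipids = [mol for sp in species for mol in topology.lipid_molecules(sp)]
    if not residues or not lipids:
        raise SelectionError("no residues or no lipid molecules selected")
    frame_dt = None
    if trajectory.time_ps is not None and trajectory.n_frames > 1:
        frame_dt = float(np.mean(np.diff(trajectory.time_ps))) / 1000.0
    events: dict = {}
    for res in residues:
        for lip in lipids:
            d = min_distance_series(trajectory, topology, res, lip)
            evs = book_events(d, criteria, res, lip)
            if evs:
                events[(res, lip)] = evs
    return contact_stats(events, trajectory.n_frames, topology, estimator, frame_dt)


def hotspot_flags(
    stats: list[ContactStats], occ_threshold: float, res_threshold: float
) -> set[tuple[tuple[str, int], str]]:
    """Residues whose occupancy AND residence time both meet the thresholds,
    per species.  The thresholds are user parameters (species-specific: weak
    binders such as cholesterol warrant lower cut-offs than DOPC)."""
    if occ_threshold < 0 or res_threshold < 0:
        raise AnalysisError("thresholds must be non-negative")
    return {
        (s.residue, s.species)
        for s in stats
        if s.occupancy_pct >= occ_threshold and s.residence_frames >= res_threshold
    }


def stats_to_frame(stats: list[ContactStats], topology: Topology | None = None) -> pd.DataFrame:
    rows = []
    for s in stats:
        chain, seq = s.residue
        rname = ""
        if topology is not None and (chain, seq) in topology.residue_index:
            rname = topology.atoms[topology.residue_index[(chain, seq)][0]].residue_name
        rows.append(
            {
                "chain": chain,
                "residue_seq": seq,
                "residue_name": rname,
                "species": s.species,
                "occupancy_pct": s.occupancy_pct,
                "residence_frames": s.residence_frames,
                "residence_ns": s.residence_ns,
                "n_events": s.n_events,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chain",
            "residue_seq",
            "residue_name",
            "species",
            "occupancy_pct",
            "residence_frames",
            "residence_ns",
            "n_events",
        ],
    )
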