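"""Dual-cutoff contact booking, distance series and occupancy/residence
statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpitraj import (
    ContactCriteria,
    ContactKineticsSpec,
    Trajectory,
    analyse_contacts,
    book_events,
    contact_stats,
    hotspot_flags,
    make_contact_trajectory,
    min_distance_series,
)
from gpitraj.contacts import ContactEvent, survival_residence_time
from gpitraj.errors import AnalysisError
from conftest import make_topology, single_atom_residues


def _two_residue_system(res_xyz, lip_xyz, box=None):
    topo = make_topology(
        single_atom_residues(1) + single_atom_residues(1, chain="L", resname="DOPC",
                                                       roles=("lipid",), name="PO4",
                                                       element="P")
    )
    coords = np.array([[res_xyz, lip_xyz]], dtype=float)
    return topo, Trajectory(coords=coords, box=box)


class TestMinDistance:
    def test_plain_euclidean(self):
        topo, traj = _two_residue_system([0, 0, 0], [0.3, 0, 0])
        d = min_distance_series(traj, topo, ("A", 1), ("L", 1))
        assert np.allclose(d, [0.3])

    def test_minimum_image(self):
        topo, traj = _two_residue_system([0, 0, 0], [0.4, 0, 0],
                                         box=np.array([[0.5, 10.0, 10.0]]))
        d = min_distance_series(traj, topo, ("A", 1), ("L", 1))
        assert np.allclose(d, [0.1])

    def test_matches_brute_force_scan(self, rng):
        n = 10
        topo = make_topology(
            [("C%d" % i, "C", 1, "ALA", "A", {"protein"}) for i in range(n)]
            + [("L%d" % i, "C", 1, "DOPC", "L", {"lipid"}) for i in range(n)]
        )
        coords = rng.uniform(0, 3.0, size=(4, 2 * n, 3))
        box = rng.uniform(2.0, 4.0, size=(4, 3))
        traj = Trajectory(coords=coords, box=box)
        d = min_distance_series(traj, topo, ("A", 1), ("L", 1))
        for f in range(4):
            best = np.inf
            for i in range(n):
                for j in range(n, 2 * n):
                    delta = coords[f, i] - coords[f, j]
                    delta -= box[f] * np.round(delta / box[f])
                    best = min(best, np.linalg.norm(delta))
            assert np.isclose(d[f], best)


class TestBookEvents:
    def test_hand_traced_hysteresis(self):
        events = book_events(np.array([0.40, 0.60, 0.90, 1.20]))
        assert [(e.start_frame, e.end_frame) for e in events] == [(0, 3)]
        assert events[0].duration == 3

    def test_never_below_lower_no_event(self):
        assert book_events(np.array([0.80, 0.95, 0.90])) == []

    def test_always_bound_single_event(self):
        events = book_events(np.full(7, 0.30))
        assert [(e.start_frame, e.end_frame) for e in events] == [(0, 7)]

    def test_equal_cutoffs_degenerate_to_thresholding(self, rng):
        d = rng.uniform(0.2, 1.5, size=200)
        cut = 0.7
        events = book_events(d, ContactCriteria(lower_cutoff=cut, upper_cutoff=cut))
        mask = np.zeros(len(d), dtype=bool)
        for e in events:
            mask[e.start_frame:e.end_frame] = True
        assert np.array_equal(mask, d < cut)

    def test_non_finite_rejected(self):
        with pytest.raises(AnalysisError):
            book_events(np.array([0.3, np.nan]))

    @settings(max_examples=60, deadline=None)
    @given(
        d=st.lists(st.floats(0.05, 2.0), min_size=1, max_size=60),
        lo=st.floats(0.2, 0.8),
        hi_delta=st.floats(0.0, 0.8),
        widen=st.floats(0.01, 0.5),
    )
    def test_cutoff_monotonicity(self, d, lo, hi_delta, widen):
        """Raising the upper cutoff never shortens an event; lowering the
        lower cutoff never creates one (entries only get rarer)."""
        d = np.array(d)
        base = ContactCriteria(lower_cutoff=lo, upper_cutoff=lo + hi_delta)
        ev1 = book_events(d, base)
        ev_wide = book_events(d, ContactCriteria(lo, lo + hi_delta + widen))
        # every original event is contained in exactly one widened event
        for e in ev1:
            assert any(w.start_frame <= e.start_frame and w.end_frame >= e.end_frame
                       for w in ev_wide)
        in1 = sum(e.duration for e in ev1)
        assert sum(e.duration for e in ev_wide) >= in1
        if lo - widen > 0:
            ev_strict = book_events(d, ContactCriteria(lo - widen, lo + hi_delta))
            assert len(ev_strict) <= len(ev1)

    @settings(max_examples=40, deadline=None)
    @given(d=st.lists(st.floats(0.05, 2.0), min_size=1, max_size=80))
    def test_events_disjoint_and_bounded(self, d):
        events = book_events(np.array(d))
        for a, b in zip(events, events[1:]):
            assert a.end_frame <= b.start_frame
        assert sum(e.duration for e in events) <= len(d)


class TestContactStats:
    def _topo(self, n_lipids=1):
        return make_topology(
            single_atom_residues(1)
            + single_atom_residues(n_lipids, chain="L", resname="DOPC",
                                   roles=("lipid",), name="PO4", element="P")
        )

    def test_single_event_counts(self):
        topo = self._topo()
        events = {(("A", 1), ("L", 1)): [ContactEvent(("A", 1), ("L", 1), 0, 3)]}
        (s,) = contact_stats(events, 10, topo)
        assert (s.occupancy_pct, s.residence_frames, s.n_events) == (30.0, 3.0, 1)

    def test_union_of_frames_over_molecules(self):
        topo = self._topo(n_lipids=2)
        events = {
            (("A", 1), ("L", 1)): [ContactEvent(("A", 1), ("L", 1), 0, 2)],
            (("A", 1), ("L", 2)): [ContactEvent(("A", 1), ("L", 2), 5, 7)],
        }
        (s,) = contact_stats(events, 10, topo)
        assert (s.occupancy_pct, s.residence_frames, s.n_events) == (40.0, 2.0, 2)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(AnalysisError):
            contact_stats({}, 0, self._topo())

    def test_markov_fixture_end_to_end(self):
        spec = ContactKineticsSpec(p_on=0.05, p_off=0.10, n_frames=20_000,
                                   n_pairs=2, seed=17)
        topo, traj, states = make_contact_trajectory(spec)
        stats = analyse_contacts(traj, topo, ["DOPC"])
        for s in stats:
            p = s.residue[1] - 1
            assert s.occupancy_pct == pytest.approx(100.0 * states[p].mean(), abs=1e-9)
        # pooled occupancy near the stationary value, dwell near 1/p_off
        occ = np.mean([s.occupancy_pct for s in stats])
        res = np.mean([s.residence_frames for s in stats])
        assert abs(occ - 100.0 / 3.0) < 2.5
        assert abs(res - 10.0) < 1.0

    def test_survival_estimator_close_to_geometric_mean_dwell(self):
        rng = np.random.default_rng(23)
        durations = rng.geometric(0.1, size=4000)
        tau = survival_residence_time(durations)
        assert abs(tau - 10.0) < 2.0


class TestHotspots:
    def test_threshold_extremes(self):
        spec = ContactKineticsSpec(p_on=0.05, p_off=0.1, n_frames=3000, n_pairs=4, seed=2)
        topo, traj, _ = make_contact_trajectory(spec)
        stats = analyse_contacts(traj, topo, ["DOPC"])
        assert hotspot_flags(stats, 0.0, 0.0) == {
            (s.residue, s.species) for s in stats if s.n_events > 0
        }
        assert hotspot_flags(stats, 101.0, 0.0) == set()

    def test_planted_hot_population_separates(self):
        cold = ContactKineticsSpec(p_on=0.005, p_off=0.2, n_frames=5000,
                                   n_pairs=45, seed=31)
        hot = ContactKineticsSpec(p_on=0.05, p_off=0.2, n_frames=5000,
                                  n_pairs=5, seed=32)
        t1, traj1, _ = make_contact_trajectory(cold)
        t2, traj2, _ = make_contact_trajectory(hot)
        stats = analyse_contacts(traj1, t1, ["DOPC"]) + [
            # shift hot residues to ids 46..50 to emulate one 50-residue system
            type(s)(residue=("A", s.residue[1] + 45), species=s.species,
                    occupancy_pct=s.occupancy_pct,
                    residence_frames=s.residence_frames, n_events=s.n_events)
            for s in analyse_contacts(traj2, t2, ["DOPC"])
        ]
        # stationary occupancies: cold ~2.4%, hot ~20%; threshold in between
        flagged = hotspot_flags(stats, occ_threshold=10.0, res_threshold=0.0)
        assert {r[0][1] for r in flagged} == {46, 47, 48, 49, 50}
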