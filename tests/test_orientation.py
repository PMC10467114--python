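"""Kabsch superposition, Euler decomposition and the orientation landscape."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpitraj import (
    OrientationMixtureSpec,
    build_landscape,
    euler_from_rotation,
    frames_near,
    kabsch_superpose,
    make_ca_body,
    make_orientation_trajectory,
    pose_series,
)
from gpitraj.errors import AnalysisError, DegenerateBodyError, StructureError
from gpitraj.geometry import compose_zyx, pose_distance


class TestKabsch:
    def test_identity_on_self(self):
        _, body = make_ca_body(10, seed=1)
        R, t, rmsd = kabsch_superpose(body, body)
        assert np.abs(R - np.eye(3)).max() < 1e-12
        assert np.abs(t).max() < 1e-12 and rmsd < 1e-12

    def test_exact_recovery_of_rotation_and_translation(self, rng):
        _, body = make_ca_body(10, seed=2)
        R_true = compose_zyx(*rng.uniform(-180, 180, 3))
        t_true = rng.uniform(-3, 3, 3)
        mobile = body @ R_true.T + t_true
        R, t, rmsd = kabsch_superpose(mobile, body)
        assert np.abs(R - R_true.T).max() < 1e-8
        assert rmsd < 1e-8
        assert np.abs(mobile @ R.T + t - body).max() < 1e-8

    def test_proper_rotation_even_for_reflected_noise(self, rng):
        # near-planar body plus noise can push naive SVD to a reflection
        body = rng.normal(size=(20, 3)) * np.array([1.0, 1.0, 1e-3])
        mobile = body @ compose_zyx(10.0, 170.0, 5.0).T + rng.normal(0, 0.05, (20, 3))
        R, _, _ = kabsch_superpose(mobile, body)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_optimal_among_probe_rotations(self, rng):
        _, body = make_ca_body(10, seed=3)
        mobile = body @ compose_zyx(40.0, -20.0, 75.0).T + rng.normal(0, 0.01, body.shape)
        R, t, rmsd = kabsch_superpose(mobile, body)
        centred_m = mobile - mobile.mean(axis=0)
        centred_b = body - body.mean(axis=0)
        for _ in range(200):
            P = Rotation.random(random_state=rng).as_matrix()
            probe_rmsd = np.sqrt(np.mean(np.sum((centred_m @ P.T - centred_b) ** 2, axis=1)))
            assert rmsd <= probe_rmsd + 1e-12

    def test_collinear_rejected(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateBodyError):
            kabsch_superpose(line, line)

    def test_size_mismatch_rejected(self):
        _, body = make_ca_body(6, seed=1)
        with pytest.raises(StructureError):
            kabsch_superpose(body[:5], body)


class TestEulerDecomposition:
    @pytest.mark.parametrize(
        "R,expected",
        [(np.eye(3), (0.0, 0.0)),
         (compose_zyx(0.0, 30.0, 0.0), (30.0, 0.0)),
         (compose_zyx(0.0, 0.0, 45.0), (0.0, 45.0))],
    )
    def test_elementary_rotations(self, R, expected):
        pose = euler_from_rotation(R)
        assert (pose.theta, pose.psi) == pytest.approx(expected, abs=1e-12)

    def test_composition_oracle_z_rotation_invisible(self, rng):
        """Recovered (theta, psi) must match the generating angles to 1e-9 deg
        for any z-rotation phi, cross-checked against scipy's intrinsic
        Z-Y-X convention."""
        for _ in range(300):
            phi = rng.uniform(-180, 180)
            theta = rng.uniform(-89, 89)
            psi = rng.uniform(-179.9, 180)
            R = compose_zyx(phi, theta, psi)
            pose = euler_from_rotation(R)
            assert abs(pose.theta - theta) < 1e-9
            assert abs(pose.psi - psi) < 1e-9
            sp = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
            assert pose.theta == pytest.approx(sp[1], abs=1e-9)
            assert pose.psi == pytest.approx(sp[2], abs=1e-9)

    def test_gimbal_lock_flagged(self):
        pose = euler_from_rotation(compose_zyx(25.0, 90.0, 40.0))
        assert pose.gimbal_flag and pose.psi == 0.0
        assert abs(pose.theta) == pytest.approx(90.0, abs=1e-6)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(StructureError):
            euler_from_rotation(np.eye(3) * 1.01)


def _mixture_landscape(n_frames=2000, stdev=10.0, seed=7):
    spec = OrientationMixtureSpec(
        components=((-30.0, 40.0, stdev, 0.5), (45.0, -120.0, stdev, 0.5)),
        n_frames=n_frames, seed=seed)
    topo, traj, truth = make_orientation_trajectory(spec)
    _, ref = make_ca_body(16, seed=seed)
    return topo, traj, truth, ref


class TestLandscape:
    def test_identical_frames_single_mode_at_origin(self):
        _, body = make_ca_body(8, seed=1)
        from gpitraj.model import Trajectory
        from conftest import make_topology, single_atom_residues

        topo = make_topology(single_atom_residues(8))
        traj = Trajectory(coords=np.repeat(body[None], 5, axis=0))
        ls = build_landscape(traj, topo, body)
        assert all(p.theta == pytest.approx(0, abs=1e-9) for p in ls.poses)
        assert len(ls.modes) == 1
        assert (ls.modes[0]["theta"], ls.modes[0]["psi"]) == (0.0, 0.0)

    def test_density_normalised(self):
        topo, traj, _, ref = _mixture_landscape(n_frames=400)
        ls = build_landscape(traj, topo, ref)
        cell = 1.0  # deg^2 grid spacing
        assert ls.density.sum() * cell == pytest.approx(1.0, abs=1e-3)
        assert (ls.density >= 0).all()

    def test_mixture_mode_recovery_and_purity(self):
        topo, traj, truth, ref = _mixture_landscape()
        ls = build_landscape(traj, topo, ref)
        assert len(ls.modes) == 2
        planted = [(-30.0, 40.0), (45.0, -120.0)]
        comp_label = truth.set_index("frame").component
        matched = set()
        for mode in ls.modes:
            d = [pose_distance(mode["theta"], mode["psi"], t, p) for t, p in planted]
            j = int(np.argmin(d))
            assert d[j] <= 3.0
            matched.add(j)
            labels = comp_label.loc[mode["members"]]
            assert (labels == j).mean() >= 0.95
        assert matched == {0, 1}

    def test_mode_count_invariant_to_phi(self):
        # same (theta, psi) cluster, phi uniform: z-rotation must not split modes
        spec = OrientationMixtureSpec(components=((20.0, -50.0, 8.0, 1.0),),
                                      n_frames=800, seed=5)
        topo, traj, _ = make_orientation_trajectory(spec)
        _, ref = make_ca_body(16, seed=5)
        ls = build_landscape(traj, topo, ref)
        assert len(ls.modes) == 1

    def test_pipeline_exact_inverse_at_vanishing_noise(self):
        spec = OrientationMixtureSpec(
            components=((-30.0, 40.0, 1e-6, 0.5), (45.0, -120.0, 1e-6, 0.5)),
            n_frames=200, seed=21)
        topo, traj, truth = make_orientation_trajectory(spec)
        _, ref = make_ca_body(16, seed=21)
        poses = pose_series(traj, topo, ref)
        for p in poses:
            assert abs(p.theta - truth.theta_deg[p.frame]) < 1e-6
            assert abs(p.psi - truth.psi_deg[p.frame]) < 1e-6

    def test_empty_alignment_selection(self):
        topo, traj, _, ref = _mixture_landscape(n_frames=5)
        with pytest.raises(AnalysisError):
            pose_series(traj, topo, ref, align_sel="name ZZ")


class TestFramesNear:
    def _landscape(self):
        topo, traj, truth, ref = _mixture_landscape(n_frames=300, seed=9)
        return build_landscape(traj, topo, ref), truth

    def test_exact_pose_is_its_own_nearest(self):
        ls, _ = self._landscape()
        p = ls.poses[42]
        assert frames_near(ls, (p.theta, p.psi), 1) == [p.frame]

    def test_psi_wraps_across_180(self):
        assert pose_distance(0.0, 179.0, 0.0, -179.0) == pytest.approx(2.0)
        assert pose_distance(0.0, 179.0, 0.0, -179.0) != pytest.approx(358.0)

    def test_full_ordering_matches_brute_force(self):
        ls, _ = self._landscape()
        target = (10.0, 170.0)
        got = frames_near(ls, target, len(ls.poses))
        d = {p.frame: pose_distance(p.theta, p.psi, *target) for p in ls.poses}
        brute = sorted(d, key=lambda f: d[f])
        assert [d[f] for f in got] == pytest.approx([d[f] for f in brute])

    def test_k_larger_than_n_truncates(self):
        ls, _ = self._landscape()
        assert len(frames_near(ls, (0.0, 0.0), len(ls.poses) + 50)) == len(ls.poses)
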