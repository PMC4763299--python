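import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from statescan import (Trajectory, angle_series, kabsch_superpose,
                       pair_distance_series, rmsd_series, rmsf_profile)
from statescan.geometry import align_frames
from conftest import make_topology, make_trajectory
from oracles import superposed_rmsd_grid, superposed_rmsd_scipy


def _model(coords):
    from statescan import StructureModel
    return StructureModel(make_topology(len(coords)), np.asarray(coords, float))


def _random_rigid(rng):
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-10, 10, 3)
    return rot, trans


class TestKabschSuperpose:
    def test_identity(self, rng):
        m = _model(rng.uniform(-5, 5, (6, 3)))
        result, moved = kabsch_superpose(m, m, np.arange(6))
        assert result.rmsd_after == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(result.rotation, np.eye(3), atol=1e-8)
        assert np.allclose(result.translation, 0.0, atol=1e-8)
        assert np.allclose(moved.coords, m.coords, atol=1e-10)

    def test_isometry_removed(self, rng):
        ref = _model(rng.uniform(-5, 5, (8, 3)))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = _model(ref.coords @ rot.T + np.array([1.0, 2.0, 3.0]))
        result, moved = kabsch_superpose(mobile, ref, np.arange(8))
        assert result.rmsd_after == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(moved.coords, ref.coords, atol=1e-8)

    def test_displaced_atom_matches_numerical_minimum(self):
        ref = _model([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        mob_coords = ref.coords.copy()
        mob_coords[3] += np.array([0.6, -0.8, 0.0])   # 1.0 Å displacement
        result, _ = kabsch_superpose(_model(mob_coords), ref, np.arange(4))
        oracle = superposed_rmsd_grid(mob_coords, ref.coords)
        assert result.rmsd_after == pytest.approx(oracle, abs=1e-6)

    def test_rejects_degenerate_fit_sets(self, rng):
        collinear = _model(np.outer(np.arange(4, dtype=float), [1.0, 0, 0]))
        with pytest.raises(ValueError):
            kabsch_superpose(collinear, collinear, np.arange(4))
        tiny = _model(rng.uniform(-1, 1, (4, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(tiny, tiny, np.arange(2))

    def test_rmsd_symmetry_and_rigid_invariance(self, rng):
        for _ in range(10):
            a = rng.uniform(-5, 5, (7, 3))
            b = a + rng.normal(0, 1.0, (7, 3))
            fwd, _ = kabsch_superpose(_model(a), _model(b), np.arange(7))
            rev, _ = kabsch_superpose(_model(b), _model(a), np.arange(7))
            assert fwd.rmsd_after == pytest.approx(rev.rmsd_after, abs=1e-9)
            rot, trans = _random_rigid(rng)
            moved, _ = kabsch_superpose(_model(a @ rot.T + trans), _model(b), np.arange(7))
            assert moved.rmsd_after == pytest.approx(fwd.rmsd_after, abs=1e-9)

    def test_agrees_with_scipy_fit_on_random_pairs(self, rng):
        for _ in range(20):
            a = rng.uniform(-4, 4, (6, 3))
            b = rng.uniform(-4, 4, (6, 3))
            mine, _ = kabsch_superpose(_model(a), _model(b), np.arange(6))
            assert mine.rmsd_after == pytest.approx(superposed_rmsd_scipy(a, b), rel=1e-8)


class TestRMSDSeries:
    def test_identical_frames_zero(self, rng):
        base = rng.uniform(-5, 5, (10, 3))
        traj = make_trajectory(np.repeat(base[None], 5, axis=0))
        series = rmsd_series(traj, traj[0], np.arange(10))
        assert np.allclose(series.values, 0.0, atol=1e-10)

    def test_measure_equals_fit_consistency(self, rng):
        coords = rng.uniform(-5, 5, (4, 9, 3))
        traj = make_trajectory(coords)
        series = rmsd_series(traj, traj[0], np.arange(9))
        for f in range(4):
            res, _ = kabsch_superpose(traj[f], traj[0], np.arange(9))
            assert series.values[f] == pytest.approx(res.rmsd_after, abs=1e-9)

    def test_region_restricted_rmsd_of_rigid_switch_shift(self, rng):
        static = rng.uniform(-6, 6, (20, 3))
        switch = rng.uniform(-6, 6, (5, 3))
        frame1 = np.vstack([static, switch])
        frame2 = np.vstack([static, switch + np.array([0, 0, 2.0])])
        traj = make_trajectory(np.stack([frame1, frame2]))
        series = rmsd_series(traj, traj[0], fit_sel=np.arange(20),
                             measure_sel=np.arange(20, 25))
        assert series.values[1] == pytest.approx(2.0, abs=1e-9)


class TestRMSF:
    def test_constant_trajectory_zero(self, rng):
        base = rng.uniform(-5, 5, (12, 3))
        traj = make_trajectory(np.repeat(base[None], 6, axis=0))
        profile = rmsf_profile(traj, np.arange(12), np.arange(12))
        assert np.allclose(profile.values, 0.0, atol=1e-9)

    def test_single_frame_rejected(self, rng):
        traj = make_trajectory(rng.uniform(-5, 5, (1, 8, 3)))
        with pytest.raises(ValueError):
            rmsf_profile(traj, np.arange(8), np.arange(8))

    def test_iid_noise_limit_sigma_sqrt3(self, rng):
        # large static core carries the fit; measured atoms carry iid noise
        core = rng.uniform(-8, 8, (30, 3))
        noisy = rng.uniform(-8, 8, (10, 3))
        sigma = 0.5
        frames = 2000
        coords = np.repeat(np.vstack([core, noisy])[None], frames, axis=0)
        coords[:, 30:, :] += rng.normal(0, sigma, (frames, 10, 3))
        traj = make_trajectory(coords)
        profile = rmsf_profile(traj, np.arange(30), np.arange(30, 40))
        expected = sigma * np.sqrt(3.0)
        assert np.mean(profile.values) == pytest.approx(expected, rel=0.05)

    def test_switch_exceeds_core_on_two_state_ensemble(self, two_state):
        traj = two_state.trajectory
        profile = rmsf_profile(traj, "name CA and chain A", "name CA and chain A")
        seqs = profile.residue_seqs
        switch = (seqs >= 59) & (seqs <= 67)
        core = (seqs >= 1) & (seqs <= 25)
        assert profile.values[switch].mean() > profile.values[core].mean()


class TestInternalCoordinates:
    def test_three_four_five(self):
        traj = make_trajectory(np.array([[[0, 0, 0], [3, 4, 0], [9, 9, 9]]], float))
        series = pair_distance_series(traj, np.array([0]), np.array([1]))
        assert series.values[0] == pytest.approx(5.0)

    def test_generated_d1_distance(self, base_model):
        traj = Trajectory(base_model.topology, base_model.coords[None])
        series = pair_distance_series(traj, "resseq 60 and name CA and chain A",
                                      "name PB and hetero")
        assert series.values[0] == pytest.approx(6.8, abs=1e-9)

    def test_multi_atom_selection_rejected(self, base_model):
        traj = Trajectory(base_model.topology, base_model.coords[None])
        with pytest.raises(ValueError):
            pair_distance_series(traj, "name CA", "name PB and hetero")

    def test_right_angle_and_collinear(self):
        traj = make_trajectory(np.array([[[1, 0, 0], [0, 0, 0], [0, 1, 0], [-2, 0, 0]]], float))
        a, b, c, d = (np.array([i]) for i in range(4))
        assert angle_series(traj, a, b, c).values[0] == pytest.approx(90.0)
        assert angle_series(traj, a, b, d).values[0] == pytest.approx(180.0)

    def test_coincident_atoms_rejected(self):
        traj = make_trajectory(np.zeros((1, 3, 3)))
        with pytest.raises(ValueError):
            angle_series(traj, np.array([0]), np.array([1]), np.array([2]))

    def test_angle_matches_direct_formula(self, rng):
        coords = rng.uniform(-5, 5, (50, 3, 3))
        traj = make_trajectory(coords)
        series = angle_series(traj, np.array([0]), np.array([1]), np.array([2]))
        v1 = coords[:, 0] - coords[:, 1]
        v2 = coords[:, 2] - coords[:, 1]
        expected = np.degrees(np.arccos(np.clip(
            np.sum(v1 * v2, axis=1)
            / (np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)), -1, 1)))
        assert np.allclose(series.values, expected, atol=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_internal_coordinates_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-5, 5, (3, 6, 3))
        rot, trans = _random_rigid(rng)
        moved = coords @ rot.T + trans
        t1, t2 = make_trajectory(coords), make_trajectory(moved)
        d1 = pair_distance_series(t1, np.array([0]), np.array([1])).values
        d2 = pair_distance_series(t2, np.array([0]), np.array([1])).values
        assert np.allclose(d1, d2, atol=1e-9)
        a1 = angle_series(t1, np.array([0]), np.array([2]), np.array([4])).values
        a2 = angle_series(t2, np.array([0]), np.array([2]), np.array([4])).values
        assert np.allclose(a1, a2, atol=1e-8)


def test_align_frames_matches_per_frame_kabsch(rng):
    coords = rng.uniform(-5, 5, (6, 8, 3))
    ref = rng.uniform(-5, 5, (8, 3))
    batched = align_frames(coords, ref, np.arange(8))
    from statescan import StructureModel
    ref_model = StructureModel(make_topology(8), ref)
    for f in range(6):
        _, moved = kabsch_superpose(StructureModel(make_topology(8), coords[f]),
                                    ref_model, np.arange(8))
        assert np.allclose(batched[f], moved.coords, atol=1e-9)
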