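import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from statescan import (Trajectory, average_linkage_cluster, kabsch_superpose,
                       pairwise_rmsd_matrix, representative_structure)
from statescan.evaluate import label_agreement
from conftest import make_topology, make_trajectory
from oracles import average_linkage_naive


def _two_group_distance_matrix(rng, n_a=3, n_b=3, intra=0.2, inter=4.0):
    d = np.zeros((n_a + n_b, n_a + n_b))
    for i in range(n_a + n_b):
        for j in range(i + 1, n_a + n_b):
            same = (i < n_a) == (j < n_a)
            d[i, j] = d[j, i] = (intra if same else inter) + rng.uniform(0, 0.05)
    return d


class TestPairwiseRMSD:
    def test_duplicate_and_rigidly_moved_frames_are_zero(self, rng):
        base = rng.uniform(-5, 5, (8, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        coords = np.stack([base, base.copy(), base @ rot.T + np.array([1, 2, 3.0])])
        traj = make_trajectory(coords)
        d = pairwise_rmsd_matrix(traj, np.arange(8))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-8)
        assert d[0, 2] == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(np.diag(d), 0.0)

    def test_matches_elementwise_kabsch(self, rng):
        coords = rng.uniform(-5, 5, (4, 7, 3))
        traj = make_trajectory(coords)
        d = pairwise_rmsd_matrix(traj, np.arange(7))
        from statescan import StructureModel
        for i in range(4):
            for j in range(4):
                res, _ = kabsch_superpose(traj[i], traj[j], np.arange(7))
                assert d[i, j] == pytest.approx(res.rmsd_after, abs=1e-9)

    def test_chunking_is_transparent(self, rng):
        coords = rng.uniform(-5, 5, (9, 5, 3))
        traj = make_trajectory(coords)
        d1 = pairwise_rmsd_matrix(traj, np.arange(5), chunk=2)
        d2 = pairwise_rmsd_matrix(traj, np.arange(5), chunk=100)
        assert np.allclose(d1, d2, atol=1e-12)


class TestAverageLinkage:
    def test_all_far_gives_singletons(self, rng):
        d = _two_group_distance_matrix(rng, intra=5.0, inter=9.0)
        result = average_linkage_cluster(d, threshold=1.5)
        assert result.n_clusters == 6
        assert sorted(result.labels.tolist()) == list(range(6))

    def test_all_near_gives_one_cluster(self, rng):
        d = _two_group_distance_matrix(rng, intra=0.2, inter=0.8)
        result = average_linkage_cluster(d, threshold=1.5)
        assert result.n_clusters == 1

    def test_two_groups_recovered_and_match_naive_oracle(self, rng):
        d = _two_group_distance_matrix(rng, intra=0.25, inter=3.5)
        result = average_linkage_cluster(d, threshold=1.5)
        assert result.n_clusters == 2
        assert result.labels.tolist() == [0, 0, 0, 1, 1, 1]
        oracle = average_linkage_naive(d, 1.5)
        assert np.array_equal(result.labels, oracle)

    def test_random_instances_match_naive_oracle(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = int(r.integers(4, 9))
            pts = r.uniform(0, 5, (n, 2))
            d = np.sqrt(np.sum((pts[:, None] - pts[None]) ** 2, axis=2))
            thr = float(r.uniform(0.5, 3.0))
            mine = average_linkage_cluster(d, thr).labels
            oracle = average_linkage_naive(d, thr)
            assert np.array_equal(mine, oracle), f"seed {seed}"

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            average_linkage_cluster(np.array([[0, 1.0], [2.0, 0]]), 1.0)
        with pytest.raises(ValueError):
            average_linkage_cluster(-np.ones((3, 3)), 1.0)
        with pytest.raises(ValueError):
            average_linkage_cluster(np.zeros((3, 3)), 0.0)

    def test_cluster_count_monotone_in_threshold(self, rng):
        d = _two_group_distance_matrix(rng, intra=0.4, inter=2.5)
        counts = [average_linkage_cluster(d, t).n_clusters
                  for t in (0.1, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert counts == sorted(counts, reverse=True)

    def test_invariant_under_frame_relabeling(self, rng):
        d = _two_group_distance_matrix(rng)
        perm = rng.permutation(6)
        d_perm = d[np.ix_(perm, perm)]
        labels = average_linkage_cluster(d, 1.5).labels
        labels_perm = average_linkage_cluster(d_perm, 1.5).labels
        assert label_agreement(labels_perm, labels[perm]) == 1.0


class TestRepresentatives:
    def test_singleton_cluster_is_its_own_representative(self, rng):
        coords = rng.uniform(-5, 5, (3, 6, 3))
        traj = make_trajectory(coords)
        d = pairwise_rmsd_matrix(traj, np.arange(6))
        result = average_linkage_cluster(d, threshold=1e-6)
        reps = representative_structure(traj, result, np.arange(6))
        for cid, frame in reps.items():
            assert result.labels[frame] == cid
            assert np.sum(result.labels == cid) == 1

    def test_symmetric_triplet_picks_center(self, rng):
        base = rng.uniform(-5, 5, (6, 3))
        delta = rng.normal(0, 0.3, (6, 3))
        coords = np.stack([base - delta, base, base + delta])
        traj = make_trajectory(coords)
        result = average_linkage_cluster(pairwise_rmsd_matrix(traj, np.arange(6)), 100.0)
        assert result.n_clusters == 1
        assert representative_structure(traj, result, np.arange(6), 0) == 1

    def test_matches_exhaustive_rmsd_to_average(self, rng):
        coords = rng.uniform(-5, 5, (10, 5, 3))
        coords[1:] = coords[0] + rng.normal(0, 0.5, (9, 5, 3))
        traj = make_trajectory(coords)
        result = average_linkage_cluster(pairwise_rmsd_matrix(traj, np.arange(5)), 100.0)
        rep = representative_structure(traj, result, np.arange(5), 0)

        from statescan.clustering import cluster_average_coords
        from oracles import superposed_rmsd_scipy
        avg = cluster_average_coords(traj, np.arange(10), np.arange(5))
        dists = [superposed_rmsd_scipy(traj.coords[f], avg) for f in range(10)]
        assert rep == int(np.argmin(dists))


def test_two_state_ensemble_recovers_truth(two_state):
    traj = two_state.trajectory.strided(10)
    truth = two_state.states[::10]
    d = pairwise_rmsd_matrix(traj, "name CA and chain A")
    result = average_linkage_cluster(d, 1.5)
    assert result.n_clusters == 2
    assert label_agreement(result.labels, truth) >= 0.99
    reps = representative_structure(traj, result, "name CA and chain A")
    for cid, frame in reps.items():
        assert result.labels[frame] == cid
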