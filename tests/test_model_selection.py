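"""Pose filtering, L-RMSD, k-medoids clustering and density ranking."""

import math

import numpy as np
import pytest

from conftest import kabsch_oracle
from slimdock.coarse_grain import derive_pseudo_atoms, CoarseChain, \
    random_peptide_conformation
from slimdock.docking_engine import Snapshot, Trajectory
from slimdock.model_selection import (
    Cluster,
    Pose,
    PoseSet,
    kmedoids_cluster,
    lrmsd,
    lrmsd_matrix,
    rank_and_represent,
    select_lowest_energy,
)


def _coarse_from_ca(ca, sequence="AAAA"):
    cb, sc, pb = derive_pseudo_atoms(np.asarray(ca, float), sequence)
    return CoarseChain("P", sequence, np.asarray(ca, float), cb, sc, pb)


def _fake_trajectory(energies_by_replica, rng_seed=0):
    """Snapshots with prescribed energies; receptor static, peptide random."""
    rng = np.random.default_rng(rng_seed)
    rec_ca = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [3.8, 3.8, 3.8]])
    rec = _coarse_from_ca(rec_ca)
    snapshots = []
    sid = 0
    for replica, energies in enumerate(energies_by_replica):
        for sweep, e in enumerate(energies):
            pep = _coarse_from_ca(rng.normal(size=(4, 3)) * 5)
            snapshots.append(Snapshot(snapshot_id=sid, replica=replica,
                                      sweep=sweep, energy=float(e), terms={},
                                      peptide=pep, receptor=rec.copy()))
            sid += 1
    meta = {"sequence": "AAAA", "receptor_start_ca": rec_ca.tolist(), "seed": 0}
    return Trajectory(snapshots=snapshots, metadata=meta)


class TestSelectLowestEnergy:
    def test_matches_sort_and_take(self):
        energies = [[5, 1, 3, 2, 4], [9, 7, 8, 6, 5]]
        traj = _fake_trajectory(energies)
        poses = select_lowest_energy(traj, per_replica=2)
        assert len(poses) == 4
        got = sorted((p.replica, p.energy) for p in poses.poses)
        assert got == [(0, 1.0), (0, 2.0), (1, 5.0), (1, 6.0)]

    def test_identity_selection(self):
        traj = _fake_trajectory([[3, 1, 2]])
        poses = select_lowest_energy(traj, per_replica=3)
        assert len(poses) == 3

    def test_overdraw_rejected(self):
        traj = _fake_trajectory([[1, 2]])
        with pytest.raises(ValueError):
            select_lowest_energy(traj, per_replica=3)

    def test_ties_break_by_snapshot_index(self):
        traj = _fake_trajectory([[2.0, 2.0, 2.0, 1.0]])
        poses = select_lowest_energy(traj, per_replica=2)
        assert sorted(p.snapshot_id for p in poses.poses) == [0, 3]

    def test_receptor_alignment_applied(self):
        """A rigidly rotated snapshot must come back in the start frame."""
        from scipy.spatial.transform import Rotation
        traj = _fake_trajectory([[1.0]])
        snap = traj.snapshots[0]
        r = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        t = np.array([4.0, -2.0, 9.0])
        orig_pep = snap.peptide.ca.copy()
        snap.receptor.ca[:] = snap.receptor.ca @ r.T + t
        snap.peptide.ca[:] = snap.peptide.ca @ r.T + t
        poses = select_lowest_energy(traj, per_replica=1)
        assert np.allclose(poses.poses[0].peptide_ca, orig_pep, atol=1e-8)


class TestLrmsd:
    def test_identity_is_zero(self):
        p = np.random.default_rng(0).normal(size=(6, 3))
        assert lrmsd(p, p) == 0.0

    def test_uniform_translation(self):
        p = np.random.default_rng(0).normal(size=(6, 3))
        assert lrmsd(p, p + np.array([2.0, 0, 0])) == pytest.approx(2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lrmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_matches_two_step_kabsch_oracle(self):
        """Receptor-fit-then-peptide-RMS computed independently."""
        rng = np.random.default_rng(3)
        rec_ref = rng.normal(size=(4, 3)) * 6
        for _ in range(10):
            from scipy.spatial.transform import Rotation
            r = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(size=3) * 10
            pep_a = rng.normal(size=(4, 3)) * 4
            pep_b = rng.normal(size=(4, 3)) * 4
            # snapshot b lives in a rotated frame
            rec_b = rec_ref @ r.T + t
            pep_b_moved = pep_b @ r.T + t
            # oracle: fit rec_b onto rec_ref, apply to peptide, then RMS
            ro, to, _ = kabsch_oracle(rec_b, rec_ref)
            pep_b_back = pep_b_moved @ ro.T + to
            expected = np.sqrt(np.mean(np.sum((pep_a - pep_b_back) ** 2, axis=1)))
            traj = _fake_trajectory([[1.0, 2.0]])
            traj.snapshots[0].peptide.ca[:] = pep_a
            traj.snapshots[0].receptor.ca[:] = rec_ref
            traj.snapshots[1].peptide.ca[:] = pep_b_moved
            traj.snapshots[1].receptor.ca[:] = rec_b
            traj.metadata["receptor_start_ca"] = rec_ref.tolist()
            poses = select_lowest_energy(traj, per_replica=2)
            got = lrmsd(poses.poses[0], poses.poses[1])
            assert got == pytest.approx(expected, abs=1e-6)

    def test_pseudo_metric_on_random_triples(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 7, 3)) * 5
            assert lrmsd(a, b) == pytest.approx(lrmsd(b, a))
            assert lrmsd(a, b) >= 0
            assert lrmsd(a, c) <= lrmsd(a, b) + lrmsd(b, c) + 1e-9

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(4)
        stack = rng.normal(size=(6, 5, 3)) * 3
        m = lrmsd_matrix(stack)
        for i in range(6):
            for j in range(6):
                assert m[i, j] == pytest.approx(lrmsd(stack[i], stack[j]),
                                                abs=1e-8)


def _bundle_poses(centers, n_each, spread, seed=0):
    """PoseSet with gaussian bundles of peptide conformations."""
    rng = np.random.default_rng(seed)
    poses, labels = [], []
    base = rng.normal(size=(5, 3)) * 4
    for ci, c in enumerate(centers):
        for i in range(n_each):
            ca = base + np.asarray(c) + rng.normal(scale=spread, size=(5, 3))
            poses.append(Pose(snapshot_id=len(poses), replica=0, sweep=0,
                              energy=float(rng.uniform()), peptide_ca=ca))
            labels.append(ci)
    return PoseSet(poses=poses, sequence="AAAAA",
                   receptor_start_ca=np.zeros((4, 3))), labels


class TestKMedoids:
    def test_k_equals_n_gives_singletons(self):
        poses, _ = _bundle_poses([(0, 0, 0)], 5, 1.0)
        clusters = kmedoids_cluster(poses, k=5, seed=0)
        assert len(clusters) == 5
        assert all(len(c.members) == 1 for c in clusters)
        assert all(c.density == math.inf for c in clusters)

    def test_two_separated_bundles_recovered_exactly(self):
        poses, labels = _bundle_poses([(0, 0, 0), (40, 0, 0)], 3, 0.5)
        clusters = kmedoids_cluster(poses, k=2, seed=1)
        parts = sorted(tuple(c.members) for c in clusters)
        assert parts == [(0, 1, 2), (3, 4, 5)]
        # brute force over all medoid pairs confirms optimality
        d = lrmsd_matrix(poses)
        best = min(
            (d[:, [i, j]].min(axis=1).sum(), i, j)
            for i in range(6) for j in range(i + 1, 6))
        got_cost = sum(d[c.members, c.medoid].sum() for c in clusters)
        assert got_cost == pytest.approx(best[0])

    def test_bruteforce_optimal_on_small_sets(self):
        poses, _ = _bundle_poses([(0, 0, 0), (30, 0, 0), (0, 30, 0)], 2, 0.8,
                                 seed=5)
        d = lrmsd_matrix(poses)
        clusters = kmedoids_cluster(poses, k=3, seed=2)
        got = sum(d[c.members, c.medoid].sum() for c in clusters)
        import itertools
        best = min(
            d[:, list(m)].min(axis=1).sum()
            for m in itertools.combinations(range(6), 3))
        assert got == pytest.approx(best)

    def test_deterministic_given_seed(self):
        poses, _ = _bundle_poses([(0, 0, 0), (10, 0, 0)], 10, 2.0)
        a = kmedoids_cluster(poses, k=4, seed=3)
        b = kmedoids_cluster(poses, k=4, seed=3)
        assert [c.members for c in a] == [c.members for c in b]
        assert [c.medoid for c in a] == [c.medoid for c in b]

    def test_invalid_k_rejected(self):
        poses, _ = _bundle_poses([(0, 0, 0)], 4, 1.0)
        with pytest.raises(ValueError):
            kmedoids_cluster(poses, k=5, seed=0)
        with pytest.raises(ValueError):
            kmedoids_cluster(poses, k=0, seed=0)

    def test_planted_partition_recovery(self):
        """Three well-separated basins: Rand index > 0.95 at k = 3."""
        from sklearn.metrics import rand_score
        poses, labels = _bundle_poses(
            [(0, 0, 0), (25, 0, 0), (0, 25, 0)], 20, 1.0, seed=11)
        clusters = kmedoids_cluster(poses, k=3, seed=7)
        predicted = np.empty(len(poses), dtype=int)
        for ci, c in enumerate(clusters):
            predicted[c.members] = ci
        assert rand_score(labels, predicted) > 0.95


class TestRanking:
    def test_density_formula_and_order(self):
        # crafted distance matrix: bundle A mean pairwise 1 A, bundle B 2 A
        d = np.full((10, 10), 50.0)
        np.fill_diagonal(d, 0.0)
        d[:5, :5] = 1.0 - np.eye(5)
        d[5:, 5:] = 2.0 * (1.0 - np.eye(5))
        poses, _ = _bundle_poses([(0, 0, 0)], 10, 1.0)
        clusters = kmedoids_cluster(poses, k=2, seed=0, distance_matrix=d)
        ranked = rank_and_represent(clusters, poses, k_out=2)
        assert ranked.entries[0]["density"] == pytest.approx(5.0)
        assert ranked.entries[1]["density"] == pytest.approx(2.5)

    def test_single_cluster_single_model(self):
        poses, _ = _bundle_poses([(0, 0, 0)], 6, 1.0)
        clusters = kmedoids_cluster(poses, k=1, seed=0)
        ranked = rank_and_represent(clusters, poses, k_out=10)
        assert len(ranked) == 1

    def test_singleton_sentinel_outranks_all(self):
        d = np.full((6, 6), 30.0)
        np.fill_diagonal(d, 0.0)
        d[:5, :5] = 1.0 - np.eye(5)
        poses, _ = _bundle_poses([(0, 0, 0)], 6, 1.0)
        clusters = kmedoids_cluster(poses, k=2, seed=0, distance_matrix=d)
        ranked = rank_and_represent(clusters, poses, k_out=2)
        assert ranked.entries[0]["cluster_size"] == 1
        assert ranked.entries[0]["density"] == math.inf

    def test_permutation_invariant(self):
        poses, _ = _bundle_poses([(0, 0, 0), (30, 0, 0)], 5, 1.0)
        clusters = kmedoids_cluster(poses, k=4, seed=1)
        a = rank_and_represent(clusters, poses, k_out=4)
        b = rank_and_represent(list(reversed(clusters)), poses, k_out=4)
        assert [e["pose"].snapshot_id for e in a.entries] == \
               [e["pose"].snapshot_id for e in b.entries]

    def test_medoid_membership_enforced(self):
        with pytest.raises(ValueError):
            Cluster(members=[0, 1], medoid=5, density=1.0)
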