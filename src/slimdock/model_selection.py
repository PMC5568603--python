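"""Energy filtering, L-RMSD clustering and ranking of docked poses.

From the trajectory the lowest-energy snapshots of each replica are kept
(default 100 per replica, 1000 in all), each snapshot's receptor is
superposed onto the starting receptor and the transform applied to its
peptide, so poses live in a common receptor frame.  Pairwise peptide CA
RMSD in that frame (L-RMSD) feeds a seeded k-medoids clustering, and
clusters are ranked by density = member count / mean pairwise L-RMSD.
The medoids of the densest clusters (default 10) are the representative
models.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import kabsch_superpose
from .coarse_grain import CoarseChain, coarse_to_chain, derive_pseudo_atoms
from .docking_engine import Trajectory
from .structure_io import write_pdb


@dataclass
class Pose:
    """One selected snapshot, peptide coordinates in the starting receptor frame."""

    snapshot_id: int
    replica: int
    sweep: int
    energy: float
    peptide_ca: np.ndarray


@dataclass
class PoseSet:
    poses: list[Pose]
    sequence: str
    receptor_start_ca: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.poses)

    def ca_stack(self) -> np.ndarray:
        return np.stack([p.peptide_ca for p in self.poses])


@dataclass
class Cluster:
    members: list[int]
    medoid: int
    density: float

    def __post_init__(self):
        if self.medoid not in self.members:
            raise ValueError("medoid must be a member of its cluster")


@dataclass
class RankedModels:
    """Representative poses ordered by non-increasing cluster density."""

    entries: list[dict]   # rank, cluster_size, density, medoid pose

    def __len__(self) -> int:
        return len(self.entries)

    def pose(self, rank: int) -> Pose:
        return self.entries[rank - 1]["pose"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"rank": e["rank"], "cluster_size": e["cluster_size"],
             "density": e["density"], "medoid_energy": e["pose"].energy,
             "snapshot_id": e["pose"].snapshot_id, "replica": e["pose"].replica}
            for e in self.entries])


# ---------------------------------------------------------------------------

def select_lowest_energy(trajectory: Trajectory, per_replica: int = 100) -> PoseSet:
    """The ``per_replica`` lowest-energy snapshots of each replica, aligned.

    Energy ties break by snapshot index.  Alignment: each snapshot's
    receptor CA set is superposed onto the run's starting receptor and the
    transform is applied to the snapshot's peptide CA trace.
    """
    groups = trajectory.per_replica()
    counts = {r: len(s) for r, s in groups.items()}
    if any(per_replica > c for c in counts.values()):
        raise ValueError(
            f"per_replica={per_replica} exceeds snapshots per replica {counts}")
    start_ca = trajectory.receptor_start_ca()
    poses = []
    for r in sorted(groups):
        chosen = sorted(groups[r], key=lambda s: (s.energy, s.snapshot_id))[:per_replica]
        for s in sorted(chosen, key=lambda s: s.snapshot_id):
            sup = kabsch_superpose(s.receptor.ca, start_ca)
            poses.append(Pose(snapshot_id=s.snapshot_id, replica=s.replica,
                              sweep=s.sweep, energy=s.energy,
                              peptide_ca=sup.apply(s.peptide.ca)))
    return PoseSet(poses=poses, sequence=trajectory.metadata["sequence"],
                   receptor_start_ca=start_ca,
                   metadata={"per_replica": per_replica,
                             "seed": trajectory.metadata.get("seed")})


def lrmsd(pose_a, pose_b) -> float:
    """Peptide CA RMSD between two receptor-aligned poses (no further fitting)."""
    a = pose_a.peptide_ca if isinstance(pose_a, Pose) else np.asarray(pose_a, float)
    b = pose_b.peptide_ca if isinstance(pose_b, Pose) else np.asarray(pose_b, float)
    if a.shape != b.shape:
        raise ValueError(f"peptide length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def lrmsd_matrix(poses: PoseSet | np.ndarray) -> np.ndarray:
    """Full pairwise L-RMSD matrix (the dominant clustering cost), vectorized."""
    stack = poses.ca_stack() if isinstance(poses, PoseSet) else np.asarray(poses)
    n, m, _ = stack.shape
    flat = stack.reshape(n, m * 3)
    sq = np.einsum("ij,ij->i", flat, flat)
    g = flat @ flat.T
    d2 = (sq[:, None] + sq[None, :] - 2.0 * g) / m
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


# ---------------------------------------------------------------------------
# k-medoids

def _kpp_init(d: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    n = d.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        dist = d[:, medoids].min(axis=1) ** 2
        total = dist.sum()
        if total <= 0:
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(remaining)))
            continue
        medoids.append(int(rng.choice(n, p=dist / total)))
    return medoids


def kmedoids_cluster(poses, k: int, seed: int = 0, max_iter: int = 100,
                     distance_matrix: np.ndarray | None = None,
                     single_member_density: float = math.inf) -> list[Cluster]:
    """Seeded k-medoids (PAM-style alternation) on the L-RMSD matrix.

    k++-style initialisation, then alternate nearest-medoid assignment and
    within-cluster medoid refresh until stable (total distance-to-medoid is
    non-increasing, so termination is guaranteed).  Deterministic given the
    seed; empty clusters cannot arise because each medoid claims itself.
    """
    d = lrmsd_matrix(poses) if distance_matrix is None else np.asarray(distance_matrix)
    n = d.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} poses")
    rng = np.random.default_rng(seed)
    medoids = sorted(_kpp_init(d, k, rng))
    assign = None
    for _ in range(max_iter):
        cols = d[:, medoids]
        # each medoid claims itself even under distance ties
        new_assign = np.argmin(cols, axis=1)
        for ci, mi in enumerate(medoids):
            new_assign[mi] = ci
        new_medoids = []
        for ci in range(k):
            members = np.nonzero(new_assign == ci)[0]
            sub = d[np.ix_(members, members)]
            new_medoids.append(int(members[np.argmin(sub.sum(axis=0))]))
        new_medoids = sorted(new_medoids)
        if new_medoids == medoids and assign is not None and \
                np.array_equal(new_assign, assign):
            break
        medoids, assign = new_medoids, new_assign
    clusters = []
    for ci, mi in enumerate(medoids):
        members = sorted(int(i) for i in np.nonzero(assign == ci)[0])
        clusters.append(Cluster(members=members, medoid=mi,
                                density=_density(d, members,
                                                 single_member_density)))
    return clusters


def _density(d: np.ndarray, members: list[int], single_sentinel: float) -> float:
    m = len(members)
    if m < 2:
        return single_sentinel
    sub = d[np.ix_(members, members)]
    mean_pair = sub[np.triu_indices(m, 1)].mean()
    if mean_pair == 0:
        return single_sentinel
    return m / mean_pair


def rank_and_represent(clusters: list[Cluster], poses: PoseSet,
                       k_out: int = 10) -> RankedModels:
    """Representatives of the densest clusters, at most ``k_out`` of them.

    Ties in density break by larger membership, then lower medoid energy.
    The result depends only on the cluster set, not its ordering.
    """
    if not clusters:
        raise ValueError("no clusters to rank")
    def sort_key(c: Cluster):
        return (-c.density, -len(c.members), poses.poses[c.medoid].energy)
    ordered = sorted(clusters, key=sort_key)[:k_out]
    entries = []
    for rank, c in enumerate(ordered, start=1):
        entries.append({"rank": rank, "cluster_size": len(c.members),
                        "density": c.density, "cluster": c,
                        "pose": poses.poses[c.medoid]})
    return RankedModels(entries=entries)


# ---------------------------------------------------------------------------
# persistence

def write_representatives(ranked: RankedModels, poses: PoseSet,
                          directory, receptor_chain=None) -> None:
    """model_01.pdb ... plus ranking.tsv in ``directory``.

    Each model file holds the (coarse, CA/CB) peptide pose; when the
    starting receptor chain is given it is included as a second chain.
    """
    os.makedirs(directory, exist_ok=True)
    frame = ranked.to_frame()
    frame.to_csv(os.path.join(directory, "ranking.tsv"), sep="\t", index=False,
                 float_format="%.6g")
    for e in ranked.entries:
        pose = e["pose"]
        cb, sc, pb = derive_pseudo_atoms(pose.peptide_ca, poses.sequence)
        pep = CoarseChain("P", poses.sequence, pose.peptide_ca, cb, sc, pb)
        chains = [coarse_to_chain(pep)]
        if receptor_chain is not None:
            chains.insert(0, receptor_chain)
        write_pdb(chains, os.path.join(directory, f"model_{e['rank']:02d}.pdb"),
                  remarks=[f"RANK {e['rank']} DENSITY {e['density']:.4g} "
                           f"SNAPSHOT {pose.snapshot_id}"])
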