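"""Average-linkage conformational clustering on pairwise Cα RMSD.

Snapshots are compared by optimal pairwise superposition; the resulting
frame-frame RMSD matrix is clustered agglomeratively with average linkage
(UPGMA: inter-cluster distance is the unweighted mean over all cross pairs),
cutting the dendrogram at a height threshold (1.5 Å by default downstream).
Each cluster is summarized by the member closest to the cluster-average
coordinates after rigid-body alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import align_frames, kabsch_rotation
from .io import Trajectory
from .selection import Selection, select_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "average_linkage_cluster",
    "representative_structure",
]


@dataclass
class ClusterResult:
    """Flat clustering of frames plus the agglomeration trace."""

    labels: np.ndarray                 # dense ids in [0, n_clusters)
    n_clusters: int
    merge_history: list[tuple[int, int, float]]
    representatives: dict[int, int] | None = None

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.labels)),
                             "cluster_id": self.labels})


def pairwise_rmsd_matrix(traj: Trajectory,
                         sel: Selection | str | np.ndarray = "name CA",
                         chunk: int = 64) -> np.ndarray:
    """Symmetric matrix of minimum (superposed) RMSD between all frame pairs.

    Uses the closed-form identity rmsd² = (T_i + T_j − 2·tr Σ̃_ij)/n with
    Σ̃ the reflection-corrected singular values of the cross-covariance of
    the centered selected coordinates, evaluated in row blocks so memory
    stays bounded.
    """
    if traj.n_frames < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    if isinstance(sel, (Selection, str)):
        idx = select_atoms(traj, sel)
    else:
        idx = np.asarray(sel, dtype=int)
    if idx.size < 3:
        raise ValueError("selection must contain >= 3 atoms")

    x = traj.coords[:, idx, :]
    x = x - x.mean(axis=1, keepdims=True)
    n_frames, n_atoms = x.shape[0], x.shape[1]
    t = np.einsum("fai,fai->f", x, x)

    out = np.zeros((n_frames, n_frames))
    for start in range(0, n_frames, chunk):
        stop = min(start + chunk, n_frames)
        h = np.einsum("iak,jal->ijkl", x[start:stop], x)      # cross-covariances
        u, s, vt = np.linalg.svd(h)
        det = np.linalg.det(u @ vt)
        corrected = s.sum(axis=-1) - 2.0 * s[..., 2] * (det < 0)
        sq = (t[start:stop, None] + t[None, :] - 2.0 * corrected) / n_atoms
        out[start:stop] = np.sqrt(np.clip(sq, 0.0, None))
    out = 0.5 * (out + out.T)                                  # enforce exact symmetry
    np.fill_diagonal(out, 0.0)
    return out


def average_linkage_cluster(dist: np.ndarray, threshold: float) -> ClusterResult:
    """Agglomerative average-linkage clustering of a distance matrix.

    Merging proceeds while the minimal inter-cluster average distance is at
    most ``threshold``; clusters are therefore the flat cut of the UPGMA
    dendrogram at that height.  Labels are renumbered densely in order of
    first frame appearance.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(dist < 0):
        raise ValueError("distance matrix must be non-negative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    n = dist.shape[0]
    if n == 1:
        return ClusterResult(np.zeros(1, dtype=int), 1, [])
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=threshold, criterion="distance")

    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for frame, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[frame] = remap[r]
    history = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return ClusterResult(labels, len(remap), history)


def cluster_average_coords(traj: Trajectory, members: np.ndarray,
                           idx: np.ndarray) -> np.ndarray:
    """Average selected coordinates of a cluster after rigid-body alignment.

    Members are aligned to the first member, averaged, then re-aligned once
    to that average before the final mean (averaging unaligned coordinates
    would mix overall rotation into the shape average).
    """
    coords = traj.coords[members]
    aligned = align_frames(coords, coords[0], idx)
    mean = aligned.mean(axis=0)
    aligned = align_frames(coords, mean, idx)
    return aligned.mean(axis=0)


def representative_structure(traj: Trajectory, result: ClusterResult,
                             sel: Selection | str | np.ndarray = "name CA",
                             cluster_id: int | None = None) -> int | dict[int, int]:
    """Frame(s) minimizing superposed RMSD to the cluster-average coordinates.

    With ``cluster_id`` given, returns that cluster's representative frame
    index; otherwise a dict for all clusters.  Ties break to the lowest
    frame index.
    """
    if isinstance(sel, (Selection, str)):
        idx = select_atoms(traj, sel)
    else:
        idx = np.asarray(sel, dtype=int)

    wanted = [cluster_id] if cluster_id is not None else sorted(set(result.labels.tolist()))
    reps: dict[int, int] = {}
    for cid in wanted:
        members = np.flatnonzero(result.labels == cid)
        if members.size == 0:
            raise ValueError(f"cluster {cluster_id} does not exist")
        if members.size == 1:
            reps[cid] = int(members[0])
            continue
        avg = cluster_average_coords(traj, members, idx)
        avg_sel = avg[idx] - avg[idx].mean(axis=0)
        best_frame, best_rmsd = int(members[0]), np.inf
        for f in members:
            p = traj.coords[f, idx, :]
            p = p - p.mean(axis=0)
            rot = kabsch_rotation(p, avg_sel)
            rmsd = float(np.sqrt(np.mean(np.sum((p @ rot.T - avg_sel) ** 2, axis=1))))
            if rmsd < best_rmsd - 1e-12:
                best_rmsd = rmsd
                best_frame = int(f)
        reps[cid] = best_frame
    if cluster_id is not None:
        return reps[cluster_id]
    return reps
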