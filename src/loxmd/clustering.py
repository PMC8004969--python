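"""Substrate binding-mode clustering.

Frames are compared by pairwise heavy-atom RMSD after optimal superposition
and grouped with the neighbour-counting (Daura/GROMOS-style) algorithm at a
fixed cutoff — the de facto standard for cutoff-based conformational
clustering of MD trajectories.  All tie-breaks are deterministic (lowest
frame index) so results are bit-reproducible.  The representative structure
of the most populated cluster is its centroid: the member minimizing the sum
of RMSD to all other members.

Two superposition modes are supported: fitting on the measured selection
itself (pure ligand-conformation clustering, the default) or fitting on a
separate selection (e.g. binding-pocket backbone) and measuring the ligand
RMSD without refit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InputError, LoxmdError
from .geometry import rmsd as plain_rmsd
from .geometry import superpose
from .trajectory import Address, Frame, Trajectory

__all__ = ["CLUSTER_CUTOFF_A", "ClusterResult", "pairwise_rmsd", "cluster_frames", "extract_centroid"]

#: Default neighbour cutoff (Å) for binding-mode clustering.
CLUSTER_CUTOFF_A = 0.5


@dataclass(frozen=True)
class ClusterResult:
    """Partition of frames into clusters, id 0 = most populated."""

    labels: np.ndarray  # per-frame cluster id
    sizes: np.ndarray  # per-cluster frame count, non-increasing
    centroid_frame: Optional[int] = None  # set by extract_centroid

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def pairwise_rmsd(
    traj: Trajectory,
    fit_selection: Sequence[Address],
    rmsd_selection: Optional[Sequence[Address]] = None,
) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs (Å) between all frame pairs.

    ``M[i, j]`` is the RMSD over ``rmsd_selection`` atoms of frame ``j`` after
    superposing frame ``j`` onto frame ``i`` using ``fit_selection`` atoms.
    Because the optimal fit is computed on the fit selection, M is not exactly
    symmetric when the two selections differ; it is symmetrized as
    ``(M + M.T) / 2`` with a zero diagonal.
    """
    if traj.n_frames < 2:
        raise InputError("pairwise RMSD needs at least 2 frames")
    fit_idx = traj.topology.indices(fit_selection)
    if len(fit_idx) < 3:
        raise InputError("fit selection must contain at least 3 atoms")
    meas_idx = fit_idx if rmsd_selection is None else traj.topology.indices(rmsd_selection)
    if len(meas_idx) == 0:
        raise InputError("empty RMSD selection")

    coords = traj.coords
    fit = coords[:, fit_idx]
    meas = coords[:, meas_idx]
    n = traj.n_frames
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t_ij, _ = superpose(fit[i], fit[j])  # j onto i
            d_ij = plain_rmsd(meas[i], t_ij.apply(meas[j]))
            t_ji, _ = superpose(fit[j], fit[i])  # i onto j
            d_ji = plain_rmsd(meas[j], t_ji.apply(meas[i]))
            M[i, j] = M[j, i] = 0.5 * (d_ij + d_ji)
    return M


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InputError("RMSD matrix must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise InputError("RMSD matrix must be symmetric")
    if np.any(M < 0):
        raise InputError("RMSD matrix must be non-negative")
    return M


def cluster_frames(matrix: np.ndarray, cutoff: float = CLUSTER_CUTOFF_A) -> ClusterResult:
    """Greedy neighbour-counting clustering of an RMSD matrix.

    Repeatedly the frame with the most remaining neighbours within ``cutoff``
    (ties: lowest frame index) becomes a cluster centre; the centre and its
    neighbours form a cluster and are removed.  Clusters are renumbered by
    size, descending, ties broken by earliest member frame.
    """
    M = _check_matrix(matrix)
    n = M.shape[0]
    within = M <= cutoff
    np.fill_diagonal(within, True)
    remaining = np.ones(n, dtype=bool)
    raw_clusters: list[np.ndarray] = []
    while remaining.any():
        counts = np.where(remaining, (within & remaining).sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(within[center] & remaining)
        raw_clusters.append(members)
        remaining[members] = False
    order = sorted(
        range(len(raw_clusters)),
        key=lambda k: (-len(raw_clusters[k]), int(raw_clusters[k][0])),
    )
    labels = np.empty(n, dtype=int)
    sizes = np.empty(len(raw_clusters), dtype=int)
    for new_id, k in enumerate(order):
        labels[raw_clusters[k]] = new_id
        sizes[new_id] = len(raw_clusters[k])
    return ClusterResult(labels=labels, sizes=sizes)


def extract_centroid(
    traj: Trajectory, matrix: np.ndarray, result: ClusterResult
) -> Frame:
    """Centroid frame of the most populated cluster.

    The centroid minimizes the summed RMSD to all other cluster members; ties
    go to the lowest frame index (``argmin`` convention).
    """
    M = _check_matrix(matrix)
    members = result.members(0)
    if len(members) == 0:
        raise LoxmdError("most populated cluster is empty")
    if M.shape[0] != len(result.labels) or M.shape[0] != traj.n_frames:
        raise InputError("matrix, labels and trajectory sizes disagree")
    sub = M[np.ix_(members, members)]
    centroid_pos = int(np.argmin(sub.sum(axis=1)))
    return traj.frames[int(members[centroid_pos])]
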