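"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def random_rotation(seed: int) -> np.ndarray:
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def brute_force_superposition_rmsd(ref: np.ndarray, mov: np.ndarray, n_samples: int = 400,
                                   seed: int = 0) -> float:
    """Rotation-scan RMSD oracle: dense random rotation sampling + local refinement.

    Independent of the Kabsch path: evaluates the RMSD objective directly over
    sampled rotations (translation handled by centering) and polishes the best
    candidate with a derivative-free local search on the rotation vector.
    """
    ref = ref - ref.mean(axis=0)
    mov = mov - mov.mean(axis=0)

    def objective(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = ref - mov @ R.T
        return np.sqrt((d**2).sum(axis=1).mean())

    samples = Rotation.random(n_samples, rng=np.random.default_rng(seed))
    best_vec, best_val = None, np.inf
    for rot in samples:
        val = objective(rot.as_rotvec())
        if val < best_val:
            best_val, best_vec = val, rot.as_rotvec()
    res = minimize(objective, best_vec, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    return float(min(best_val, res.fun))


def daura_oracle(matrix: np.ndarray, cutoff: float):
    """Plain-python re-implementation of neighbour-counting clustering.

    Same contract as the library routine (most neighbours wins, ties to the
    lowest index, renumber by size then earliest member) but written with
    explicit loops over frame lists so the two code paths share nothing.
    """
    n = len(matrix)
    remaining = list(range(n))
    clusters = []
    while remaining:
        best_center, best_members = None, []
        for c in remaining:
            members = [j for j in remaining if matrix[c][j] <= cutoff or j == c]
            if len(members) > len(best_members):
                best_center, best_members = c, members
        clusters.append(sorted(best_members))
        remaining = [j for j in remaining if j not in best_members]
    clusters.sort(key=lambda m: (-len(m), m[0]))
    labels = [None] * n
    for cid, members in enumerate(clusters):
        for j in members:
            labels[j] = cid
    return labels, [len(m) for m in clusters]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
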