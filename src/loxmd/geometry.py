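"""Elementary structural geometry.

Distances, optimal rigid-body superposition (Kabsch, via
``scipy.spatial.transform.Rotation.align_vectors``) and geometric assignment
of the two prochiral hydrogens on a bisallylic carbon.

The prochiral convention follows the standard pro-R/pro-S rule: a hydrogen is
pro-R if promoting it above its geminal partner (priority order
C_high > C_low > H_promoted > H_other) would make the carbon an R centre.
With unit bond vectors u1 = C->C_high, u2 = C->C_low, u3 = C->H_promoted this
reduces to the sign of the scalar triple product det[u1, u2, u3]: negative
means R (clockwise 1-2-3 when the lowest-priority hydrogen points away from
the viewer).  The ranking of the two carbon branches is supplied by the
topology (``branch_priority``), never inferred: a full CIP engine is out of
scope and the substrates of interest (arachidonic and linoleic acid) need
only a single declared branch ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError, DegenerateGeometryError, LoxmdError
from .trajectory import AUTO, Address, Frame, TopologySpec

__all__ = ["RigidTransform", "distance", "superpose", "rmsd", "assign_prochiral_hydrogens"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation + translation, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise LoxmdError("RigidTransform needs a 3x3 rotation and 3-vector translation")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise LoxmdError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise LoxmdError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def distance(p, q) -> float:
    """Euclidean distance (Å) between two points."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise DegenerateGeometryError("non-finite coordinates")
    return float(np.linalg.norm(p - q))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted, unweighted) RMSD between paired point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DegenerateGeometryError("point sets differ in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(ref: np.ndarray, mov: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper superposition of ``mov`` onto ``ref`` (Kabsch).

    Returns the rigid transform minimizing RMSD over all proper rotations and
    translations, and the minimized RMSD (Å).  Point sets must have equal
    cardinality >= 3 and must not be collinear (the rotation about a line is
    undetermined and reflection-ambiguous).
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape != mov.shape:
        raise DegenerateGeometryError("superpose needs two equally sized (n, 3) point sets")
    n = ref.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superpose needs at least 3 points")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    A = ref - ref_c
    B = mov - mov_c
    # collinear sets have rank-1 centered coordinates
    if np.linalg.matrix_rank(A, tol=1e-8) < 2 or np.linalg.matrix_rank(B, tol=1e-8) < 2:
        raise DegenerateGeometryError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(A, B)
    R = rot.as_matrix()
    transform = RigidTransform(rotation=R, translation=ref_c - R @ mov_c)
    # evaluate the objective directly: scipy's rssd carries sqrt(eps) noise
    fitted = B @ R.T
    best = float(np.sqrt(np.mean(np.sum((A - fitted) ** 2, axis=1))))
    return transform, best


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DegenerateGeometryError("zero-length bond vector")
    return v / norm


def assign_prochiral_hydrogens(
    frame: Frame, topology: TopologySpec
) -> tuple[Address, Address]:
    """Return the ``(pro-S, pro-R)`` hydrogen addresses of the reactive carbon.

    If the topology names both hydrogens explicitly this is a passthrough
    (the recommended path: force-field atom names mapped once in the config).
    With the ``AUTO`` sentinel the labels are derived geometrically from the
    declared bond list and branch priority, as described in the module
    docstring.
    """
    hS, hR = topology.h_proS, topology.h_proR
    if hS not in (None, AUTO) and hR not in (None, AUTO):
        return hS, hR
    if topology.reactive_carbon is None:
        raise ConfigError("AUTO prochiral assignment requires reactive_carbon")
    if topology.branch_priority is None:
        raise ConfigError("AUTO prochiral assignment requires branch_priority")
    if not topology.bonds:
        raise ConfigError("AUTO prochiral assignment requires a bond list (CONECT or config)")

    c_idx = topology.index(topology.reactive_carbon)
    nbrs = topology.neighbors(c_idx)
    if len(nbrs) != 4:
        raise ConfigError(
            f"reactive carbon must be tetra-coordinated, found {len(nbrs)} neighbours"
        )
    carbons = [i for i in nbrs if topology.atoms[i].element.upper() == "C"]
    hydrogens = [i for i in nbrs if topology.atoms[i].element.upper() == "H"]
    if len(carbons) != 2 or len(hydrogens) != 2:
        raise ConfigError("reactive carbon must have two C and two H neighbours")
    high_idx = topology.index(topology.branch_priority)
    if high_idx not in carbons:
        raise ConfigError("branch_priority does not name a carbon neighbour of reactive_carbon")
    low_idx = next(i for i in carbons if i != high_idx)

    c = frame.coords[c_idx]
    u1 = _unit(frame.coords[high_idx] - c)
    u2 = _unit(frame.coords[low_idx] - c)
    signs = {}
    for h in hydrogens:
        u3 = _unit(frame.coords[h] - c)
        signs[h] = float(np.linalg.det(np.column_stack([u1, u2, u3])))
    ha, hb = hydrogens
    if signs[ha] * signs[hb] >= 0:
        raise DegenerateGeometryError(
            "hydrogens are not on opposite faces; geometry is not tetrahedral"
        )
    # det < 0 -> promoting that H gives an R centre -> it is pro-R
    pro_r = ha if signs[ha] < 0 else hb
    pro_s = hb if pro_r == ha else ha
    return topology.atoms[pro_s].address, topology.atoms[pro_r].address
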