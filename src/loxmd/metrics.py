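"""Structural metrics: H-bond anchors, helix content, interface contacts.

*Anchor hydrogen bonds.*  The carboxylate head group of a bound fatty acid is
typically pinned by hydrogen bonds to a small set of polar residues (Arg405,
Lys146, Asn152, Trp145 in rabbit ALOX15).  A donor-H / acceptor pair counts
as bonded in a frame when d(H...A) <= 3.5 Å and the D-H...A angle is >= 120
degrees.  The distance cutoff is deliberately permissive so that long but
persistent carboxylate contacts (~3.3 Å) are counted; both cutoffs are
parameters.

*Helix content.*  A residue stretch is called helical through the canonical
alpha-helical i -> i+4 backbone hydrogen bond, tested geometrically:
d(O(i)...H-N(i+4)) <= 2.7 Å.  Every existing bond marks residues i..i+4 as
helical; turns are counted from the longest helical run at 3.6 residues per
turn.  This is a single-criterion assignment, not a DSSP re-implementation,
but it is exactly testable on constructed geometry.  When amide hydrogens are
absent an N-based fallback (d(O(i)...N(i+4)) <= 3.5 Å) is used and logged.

*Interface contacts.*  Per-frame distance series between two declared atoms,
e.g. the leucine-zipper pairs or the Glu181-His585 contact across the dimer
interface.  The atoms must be named explicitly in the topology: "closest
heavy atom" conventions hide which atoms a printed number refers to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InputError
from .geometry import distance
from .trajectory import Address, HelixSegment, Trajectory
from .util import round_half_up

__all__ = [
    "HBOND_DISTANCE_CUTOFF_A",
    "HBOND_ANGLE_CUTOFF_DEG",
    "HELIX_O_H_CUTOFF_A",
    "HELIX_O_N_CUTOFF_A",
    "RESIDUES_PER_TURN",
    "HBondEvent",
    "HelixMetrics",
    "ContactSeries",
    "detect_anchor_hbonds",
    "assign_helix",
    "count_turns",
    "longest_run",
    "contact_distance_series",
]

logger = logging.getLogger(__name__)

HBOND_DISTANCE_CUTOFF_A = 3.5
HBOND_ANGLE_CUTOFF_DEG = 120.0
HELIX_O_H_CUTOFF_A = 2.7
HELIX_O_N_CUTOFF_A = 3.5
RESIDUES_PER_TURN = 3.6


@dataclass(frozen=True)
class HBondEvent:
    frame_index: int
    donor: Address
    hydrogen: Address
    acceptor: Address
    d_H_A: float
    angle_DHA: float


@dataclass(frozen=True)
class HelixMetrics:
    frame_index: int
    segment: str
    helical_flags: tuple  # per-residue booleans, segment order
    longest_run: int
    n_turns: int


@dataclass(frozen=True)
class ContactSeries:
    pair: tuple
    distances: np.ndarray  # one value per frame, Å
    mean: float
    sd: float


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_anchor_hbonds(
    traj: Trajectory,
    donors: Optional[Sequence[tuple[Address, Address]]] = None,
    acceptors: Optional[Sequence[Address]] = None,
    d_cutoff: float = HBOND_DISTANCE_CUTOFF_A,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF_DEG,
) -> tuple[list[HBondEvent], dict]:
    """Detect donor-H...acceptor hydrogen bonds over all frames.

    ``donors`` are (heavy donor, bonded hydrogen) address pairs; ``acceptors``
    are acceptor heavy atoms.  Defaults come from the topology's
    ``anchor_donors`` / ``anchor_acceptors``.  Returns the event list and a
    per-(donor, acceptor) occupancy map (events / frames, in [0, 1]).
    """
    top = traj.topology
    donors = list(donors) if donors is not None else list(top.anchor_donors)
    acceptors = list(acceptors) if acceptors is not None else list(top.anchor_acceptors)
    if not donors or not acceptors:
        raise InputError("H-bond detection needs at least one donor pair and one acceptor")
    resolved = [(top.index(d), top.index(h), d, h) for d, h in donors]
    acc = [(top.index(a), a) for a in acceptors]
    events: list[HBondEvent] = []
    counts: dict[tuple, int] = {(d, a): 0 for _, _, d, _ in resolved for _, a in acc}
    for f in traj.frames:
        for di, hi, daddr, haddr in resolved:
            for ai, aaddr in acc:
                d_ha = distance(f.coords[hi], f.coords[ai])
                if d_ha > d_cutoff:
                    continue
                ang = _angle_deg(f.coords[di], f.coords[hi], f.coords[ai])
                if ang < angle_cutoff:
                    continue
                events.append(
                    HBondEvent(f.index, daddr, haddr, aaddr, d_ha, ang)
                )
                counts[(daddr, aaddr)] += 1
    n = traj.n_frames
    occupancy = {pair: c / n for pair, c in counts.items()}
    return events, occupancy


def longest_run(flags: Sequence[bool]) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def count_turns(flags: Sequence[bool]) -> int:
    """Helical turns from the longest contiguous helical run (3.6 res/turn)."""
    return int(round_half_up(longest_run(flags) / RESIDUES_PER_TURN, 0))


def _helix_flags_one_frame(coords, o_idx, h_idx, n_res, use_h) -> tuple:
    cutoff = HELIX_O_H_CUTOFF_A if use_h else HELIX_O_N_CUTOFF_A
    flags = [False] * n_res
    for i in range(n_res - 4):
        oi = o_idx[i]
        hj = h_idx[i + 4]
        if oi is None or hj is None:
            continue
        if distance(coords[oi], coords[hj]) <= cutoff:
            # an i -> i+4 backbone H-bond puts residues i..i+4 in the helix
            for k in range(i, i + 5):
                flags[k] = True
    return tuple(flags)


def assign_helix(traj: Trajectory, segment: HelixSegment) -> list[HelixMetrics]:
    """Per-frame helical flags and turn counts for one helix segment."""
    top = traj.topology
    residues = list(segment.residues)
    n_res = len(residues)
    if n_res < 5:
        raise InputError(f"segment {segment.name}: need at least 5 residues")
    o_idx = [top.find_residue_atom(segment.monomer, r, "O") for r in residues]
    h_idx = [top.find_residue_atom(segment.monomer, r, "H") for r in residues]
    if all(o is None for o in o_idx):
        raise InputError(f"segment {segment.name}: no backbone O atoms found")
    use_h = any(h is not None for h in h_idx)
    if not use_h:
        h_idx = [top.find_residue_atom(segment.monomer, r, "N") for r in residues]
        if all(h is None for h in h_idx):
            raise InputError(f"segment {segment.name}: no backbone H or N atoms found")
        logger.warning(
            "segment %s: no amide hydrogens; falling back to O(i)...N(i+4) <= %.1f Å",
            segment.name,
            HELIX_O_N_CUTOFF_A,
        )
    out = []
    for f in traj.frames:
        flags = _helix_flags_one_frame(f.coords, o_idx, h_idx, n_res, use_h)
        run = longest_run(flags)
        out.append(
            HelixMetrics(
                frame_index=f.index,
                segment=segment.name,
                helical_flags=flags,
                longest_run=run,
                n_turns=count_turns(flags),
            )
        )
    return out


def contact_distance_series(
    traj: Trajectory, pair: tuple[Address, Address]
) -> ContactSeries:
    """Distance (Å) between two declared atoms in every frame, with mean/sd."""
    a, b = pair
    ia = traj.topology.index(a)
    ib = traj.topology.index(b)
    d = np.array([distance(f.coords[ia], f.coords[ib]) for f in traj.frames])
    return ContactSeries(
        pair=(Address(*a), Address(*b)),
        distances=d,
        mean=float(d.mean()),
        sd=float(d.std(ddof=0)),
    )
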