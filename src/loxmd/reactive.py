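"""Reactive-geometry classification of trajectory frames.

Lipoxygenase catalysis starts with abstraction of a bisallylic hydrogen by
the Fe(III)-bound hydroxide.  A frame is therefore scored by three distances:
d(C-OH) from the bisallylic carbon to the hydroxide oxygen, and d(H-OH) for
each of the two prochiral hydrogens on that carbon.  Two criteria classify a
frame with respect to a hydrogen X:

* well-oriented:  d(HX-OH) < d(CX-OH)   (the C-H bond points at the hydroxide)
* pre-catalytic:  d(HX-OH) <= cutoff (3 Å default) and well-oriented

The per-frame flags are aggregated as "at least one hydrogen" percentages,
which is how these statistics are conventionally tabulated; per-hydrogen
percentages are also kept.  The distance cutoff is inclusive, the orientation
comparison strict.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, LoxmdError
from .geometry import assign_prochiral_hydrogens, distance
from .trajectory import Trajectory
from .util import round_half_up

__all__ = [
    "PRECATALYTIC_CUTOFF_A",
    "ReactiveDistances",
    "FrameClass",
    "GeometrySummary",
    "SummaryComparison",
    "compute_reactive_distances",
    "classify_frame",
    "classify",
    "summarize",
    "compare_summaries",
    "distances_frame",
]

#: Default d(H-OH) cutoff (Å) for the pre-catalytic criterion.
PRECATALYTIC_CUTOFF_A = 3.0


@dataclass(frozen=True)
class ReactiveDistances:
    frame_index: int
    time_ns: float
    d_C_OH: float
    d_HproS_OH: float
    d_HproR_OH: float


@dataclass(frozen=True)
class FrameClass:
    well_oriented_S: bool
    well_oriented_R: bool
    precatalytic_S: bool
    precatalytic_R: bool

    @property
    def well_oriented_any(self) -> bool:
        return self.well_oriented_S or self.well_oriented_R

    @property
    def precatalytic_any(self) -> bool:
        return self.precatalytic_S or self.precatalytic_R


@dataclass(frozen=True)
class GeometrySummary:
    """Mean reactive distances and classification percentages of one system."""

    n_frames: int
    mean_d_C_OH: float
    mean_d_HproS_OH: float
    mean_d_HproR_OH: float
    pct_well_oriented: float
    pct_precatalytic: float
    pct_well_oriented_S: float = float("nan")
    pct_well_oriented_R: float = float("nan")
    pct_precatalytic_S: float = float("nan")
    pct_precatalytic_R: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SummaryComparison:
    """Fold changes and distance shifts between two systems (a vs. b).

    ``fold_*`` are a/b ratios of percentages; ``delta_mean_d_C_OH`` is
    b.mean - a.mean in Å (positive when system a sits closer to the
    cofactor).  ``display_*`` carry the report rounding: folds to the nearest
    integer when >= 10 else one decimal, distance shifts to one decimal.
    """

    fold_precatalytic: float
    fold_well_oriented: float
    delta_mean_d_C_OH: float

    @property
    def display_fold_precatalytic(self) -> float:
        return _display_fold(self.fold_precatalytic)

    @property
    def display_fold_well_oriented(self) -> float:
        return _display_fold(self.fold_well_oriented)

    @property
    def display_delta_mean_d_C_OH(self) -> float:
        return round_half_up(self.delta_mean_d_C_OH, 1)


def _display_fold(fold: float) -> float:
    if fold >= 10:
        return float(round_half_up(fold, 0))
    return round_half_up(fold, 1)


def compute_reactive_distances(traj: Trajectory) -> list[ReactiveDistances]:
    """Per-frame reactive distances, one record per frame, order preserved.

    Prochiral labels are assigned once (on the first frame, geometrically if
    the topology says ``AUTO``) and held fixed: the chemical identity of each
    hydrogen does not change along a trajectory.
    """
    top = traj.topology
    if top.cofactor_oxygen is None or top.reactive_carbon is None:
        raise InputError("topology must name cofactor_oxygen and reactive_carbon")
    if not traj.frames:
        raise InputError("empty trajectory")
    addr_s, addr_r = assign_prochiral_hydrogens(traj.frames[0], top)
    i_o = top.index(top.cofactor_oxygen)
    i_c = top.index(top.reactive_carbon)
    i_s = top.index(addr_s)
    i_r = top.index(addr_r)
    out = []
    for f in traj.frames:
        out.append(
            ReactiveDistances(
                frame_index=f.index,
                time_ns=f.time_ns,
                d_C_OH=distance(f.coords[i_c], f.coords[i_o]),
                d_HproS_OH=distance(f.coords[i_s], f.coords[i_o]),
                d_HproR_OH=distance(f.coords[i_r], f.coords[i_o]),
            )
        )
    return out


def classify_frame(rd: ReactiveDistances, cutoff: float = PRECATALYTIC_CUTOFF_A) -> FrameClass:
    """Apply the two reactive-geometry criteria to one frame."""
    if not all(np.isfinite([rd.d_C_OH, rd.d_HproS_OH, rd.d_HproR_OH])):
        raise InputError(f"frame {rd.frame_index}: non-finite distances")
    wo_s = rd.d_HproS_OH < rd.d_C_OH
    wo_r = rd.d_HproR_OH < rd.d_C_OH
    return FrameClass(
        well_oriented_S=wo_s,
        well_oriented_R=wo_r,
        precatalytic_S=wo_s and rd.d_HproS_OH <= cutoff,
        precatalytic_R=wo_r and rd.d_HproR_OH <= cutoff,
    )


def classify(
    rds: Sequence[ReactiveDistances], cutoff: float = PRECATALYTIC_CUTOFF_A
) -> list[FrameClass]:
    return [classify_frame(rd, cutoff) for rd in rds]


def summarize(
    rds: Sequence[ReactiveDistances], classes: Sequence[FrameClass]
) -> GeometrySummary:
    """Arithmetic distance means and classification percentages."""
    if len(rds) == 0:
        raise InputError("cannot summarize an empty frame set")
    if len(rds) != len(classes):
        raise InputError("distances and classes differ in length")
    n = len(rds)

    def pct(flags) -> float:
        return 100.0 * sum(flags) / n

    return GeometrySummary(
        n_frames=n,
        mean_d_C_OH=float(np.mean([r.d_C_OH for r in rds])),
        mean_d_HproS_OH=float(np.mean([r.d_HproS_OH for r in rds])),
        mean_d_HproR_OH=float(np.mean([r.d_HproR_OH for r in rds])),
        pct_well_oriented=pct(c.well_oriented_any for c in classes),
        pct_precatalytic=pct(c.precatalytic_any for c in classes),
        pct_well_oriented_S=pct(c.well_oriented_S for c in classes),
        pct_well_oriented_R=pct(c.well_oriented_R for c in classes),
        pct_precatalytic_S=pct(c.precatalytic_S for c in classes),
        pct_precatalytic_R=pct(c.precatalytic_R for c in classes),
    )


def compare_summaries(a: GeometrySummary, b: GeometrySummary) -> SummaryComparison:
    """Fold changes of system ``a`` relative to reference ``b``."""
    if b.pct_precatalytic <= 0:
        raise LoxmdError("reference pre-catalytic percentage is zero; fold undefined")
    if b.pct_well_oriented <= 0:
        raise LoxmdError("reference well-oriented percentage is zero; fold undefined")
    return SummaryComparison(
        fold_precatalytic=a.pct_precatalytic / b.pct_precatalytic,
        fold_well_oriented=a.pct_well_oriented / b.pct_well_oriented,
        delta_mean_d_C_OH=b.mean_d_C_OH - a.mean_d_C_OH,
    )


def distances_frame(
    rds: Sequence[ReactiveDistances], classes: Optional[Sequence[FrameClass]] = None
) -> pd.DataFrame:
    """Tabulate per-frame distances (and flags, if given) as a DataFrame."""
    df = pd.DataFrame(
        {
            "frame": [r.frame_index for r in rds],
            "time_ns": [r.time_ns for r in rds],
            "dC": [r.d_C_OH for r in rds],
            "dHS": [r.d_HproS_OH for r in rds],
            "dHR": [r.d_HproR_OH for r in rds],
        }
    )
    if classes is not None:
        df["wo_S"] = [c.well_oriented_S for c in classes]
        df["wo_R"] = [c.well_oriented_R for c in classes]
        df["pc_S"] = [c.precatalytic_S for c in classes]
        df["pc_R"] = [c.precatalytic_R for c in classes]
        df["wo_any"] = [c.well_oriented_any for c in classes]
        df["pc_any"] = [c.precatalytic_any for c in classes]
    return df
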