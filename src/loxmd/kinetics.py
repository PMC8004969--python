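"""Michaelis–Menten kinetics and size-exclusion (SEC) calibration.

Both analyses follow the model/results idiom: a model object is built from
data, ``fit()`` returns a results object carrying estimates, standard errors
and a ``summary()`` table.

*Michaelis–Menten.*  Initial rates v (s^-1 per enzyme) at substrate
concentrations S (µM) are fitted by nonlinear least squares to

    v = kcat * S / (KM + S)

with kcat the turnover number (s^-1), KM the Michaelis constant (µM) and
kcat/KM the catalytic efficiency (s^-1 µM^-1).  Initialization: kcat0 is the
maximal observed rate and KM0 the substrate concentration at half-maximal
rate (linear interpolation).  Standard errors come from the Jacobian at the
optimum (Gauss-Newton covariance).

*SEC calibration.*  The partition coefficient of a standard eluting at Ve on
a column with void volume Vo and bed volume Vt is

    Kav = (Ve - Vo) / (Vt - Vo)

and (-log10 Kav)^(1/2) is linear in the hydrodynamic radius Rh.  An ordinary
least-squares line through the standards is inverted to estimate Rh of an
unknown from its elution volume.  Base-10 logarithm by default (the
chromatography convention); the base is a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, InputError
from .util import round_half_up

__all__ = [
    "KineticsDataset",
    "MichaelisMenten",
    "MMFit",
    "catalytic_efficiency",
    "efficiency_fold_change",
    "kav",
    "SECStandard",
    "SECCalibration",
    "calibrate_sec",
    "estimate_rh",
    "read_kinetics_csv",
    "read_sec_csv",
]


# ---------------------------------------------------------------------------
# Michaelis–Menten
# ---------------------------------------------------------------------------


@dataclass
class KineticsDataset:
    """Initial-rate dataset: (S µM, v s^-1, replicate) triples."""

    substrate: str
    points: pd.DataFrame  # columns S_uM, v_per_s, replicate

    def __post_init__(self):
        required = {"S_uM", "v_per_s"}
        if not required.issubset(self.points.columns):
            raise InputError(f"kinetics data needs columns {sorted(required)}")
        if "replicate" not in self.points.columns:
            self.points = self.points.assign(replicate=1)
        if (self.points["S_uM"] <= 0).any():
            raise InputError("substrate concentrations must be positive")
        if self.points["S_uM"].nunique() < 4:
            raise InputError("need at least 4 distinct substrate concentrations")

    @property
    def S(self) -> np.ndarray:
        return self.points["S_uM"].to_numpy(dtype=float)

    @property
    def v(self) -> np.ndarray:
        return self.points["v_per_s"].to_numpy(dtype=float)


@dataclass(frozen=True)
class MMFit:
    """Results of a Michaelis–Menten fit."""

    substrate: str
    kcat: float
    KM: float
    se_kcat: float
    se_KM: float
    rss: float
    n_points: int

    @property
    def efficiency(self) -> float:
        return self.kcat / self.KM

    def summary(self) -> str:
        lines = [
            f"Michaelis-Menten fit ({self.substrate}, n={self.n_points})",
            f"  kcat     = {self.kcat:10.4f} +/- {self.se_kcat:.4f}  s^-1",
            f"  KM       = {self.KM:10.4f} +/- {self.se_KM:.4f}  uM",
            f"  kcat/KM  = {self.efficiency:10.4f}  s^-1 uM^-1"
            f"  (display {round_half_up(self.efficiency, 1)})",
            f"  RSS      = {self.rss:10.6g}",
        ]
        return "\n".join(lines)

    def predict(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.kcat * S / (self.KM + S)


class MichaelisMenten:
    """Michaelis–Menten model for one substrate's initial-rate data.

    ``weights`` selects the residual weighting: ``"none"`` (ordinary least
    squares, the default for externally supplied data) or ``"relative"``
    (residuals scaled by 1/v, the maximum-likelihood choice when measurement
    error is proportional to the rate, as in spectrophotometric assays with
    constant coefficient of variation).
    """

    def __init__(
        self,
        S: Sequence[float],
        v: Sequence[float],
        substrate: str = "",
        weights: str = "none",
    ):
        self.S = np.asarray(S, dtype=float)
        self.v = np.asarray(v, dtype=float)
        self.substrate = substrate
        if weights not in ("none", "relative"):
            raise InputError(f"unknown weighting scheme {weights!r}")
        self.weights = weights
        if self.S.shape != self.v.shape or self.S.ndim != 1:
            raise InputError("S and v must be 1-D arrays of equal length")
        if np.any(self.S <= 0):
            raise InputError("substrate concentrations must be positive")
        if len(np.unique(self.S)) < 4:
            raise InputError("need at least 4 distinct substrate concentrations")

    @classmethod
    def from_dataset(cls, dataset: KineticsDataset, weights: str = "none") -> "MichaelisMenten":
        return cls(dataset.S, dataset.v, substrate=dataset.substrate, weights=weights)

    def _initial_guess(self) -> tuple[float, float]:
        kcat0 = float(self.v.max())
        if kcat0 <= 0:
            raise FitError("all rates are <= 0; Michaelis-Menten fit is degenerate")
        half = kcat0 / 2.0
        order = np.argsort(self.S)
        S, v = self.S[order], self.v[order]
        km0 = float(S[np.argmin(np.abs(v - half))])
        # linear interpolation of S at half-maximal rate where bracketed
        for i in range(len(S) - 1):
            lo, hi = v[i], v[i + 1]
            if (lo - half) * (hi - half) <= 0 and lo != hi:
                km0 = float(S[i] + (half - lo) * (S[i + 1] - S[i]) / (hi - lo))
                break
        return kcat0, max(km0, 1e-6)

    def fit(self) -> MMFit:
        p0 = self._initial_guess()

        def model(S, kcat, KM):
            return kcat * S / (KM + S)

        sigma = None
        if self.weights == "relative":
            sigma = np.maximum(np.abs(self.v), 1e-12 * max(self.v.max(), 1.0))
        try:
            popt, pcov = optimize.curve_fit(
                model, self.S, self.v, p0=p0, sigma=sigma,
                maxfev=500 * 4, xtol=1e-10, ftol=1e-12,
            )
        except RuntimeError as exc:
            raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
        kcat, KM = (float(x) for x in popt)
        if kcat <= 0 or KM <= 0:
            raise FitError(
                f"inadmissible Michaelis-Menten estimates: kcat={kcat:.4g}, KM={KM:.4g}"
            )
        resid = self.v - model(self.S, kcat, KM)
        se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
        return MMFit(
            substrate=self.substrate,
            kcat=kcat,
            KM=KM,
            se_kcat=float(se[0]),
            se_KM=float(se[1]),
            rss=float(np.sum(resid**2)),
            n_points=len(self.S),
        )


def catalytic_efficiency(kcat: float, KM: float) -> float:
    """kcat/KM in s^-1 µM^-1 (use :func:`round_half_up` for table display)."""
    if KM <= 0:
        raise InputError("KM must be positive")
    return kcat / KM


def efficiency_fold_change(a: float, b: float) -> float:
    """Ratio of two catalytic efficiencies (a relative to reference b)."""
    if b <= 0:
        raise InputError("reference efficiency must be positive")
    return a / b


# ---------------------------------------------------------------------------
# SEC calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SECStandard:
    name: str
    Rh_A: float  # hydrodynamic radius, Å
    Ve_mL: float  # elution volume, mL


@dataclass(frozen=True)
class SECCalibration:
    """Linear calibration y = slope * Rh + intercept, y = (-log Kav)^(1/2)."""

    Vo: float
    Vt: float
    standards: tuple
    slope: float
    intercept: float
    r_squared: float
    log_base: float = 10.0

    def summary(self) -> str:
        lines = [
            f"SEC calibration (Vo={self.Vo} mL, Vt={self.Vt} mL, "
            f"{len(self.standards)} standards)",
            f"  (-log Kav)^1/2 = {self.slope:.6f} * Rh + {self.intercept:.6f}",
            f"  r^2 = {self.r_squared:.6f}",
        ]
        for s in self.standards:
            lines.append(f"    {s.name:24s} Rh = {s.Rh_A:5.1f} Å   Ve = {s.Ve_mL:.3f} mL")
        return "\n".join(lines)


def kav(Ve: float, Vo: float, Vt: float) -> float:
    """SEC partition coefficient Kav = (Ve - Vo) / (Vt - Vo)."""
    if Vt <= Vo:
        raise InputError("total volume Vt must exceed void volume Vo")
    if not (Vo <= Ve <= Vt):
        raise InputError(f"elution volume {Ve} outside [Vo={Vo}, Vt={Vt}]")
    return (Ve - Vo) / (Vt - Vo)


def _y_of_kav(k: float, base: float) -> float:
    if k <= 0:
        raise InputError("Kav = 0: log undefined (standard co-eluting with the void)")
    val = -math.log(k, base)
    if val < 0:
        raise InputError("Kav > 1: elution beyond the bed volume")
    return math.sqrt(val)


def calibrate_sec(
    standards: Sequence[SECStandard], Vo: float, Vt: float, log_base: float = 10.0
) -> SECCalibration:
    """OLS of (-log Kav)^(1/2) on Rh over >= 3 standards."""
    standards = tuple(standards)
    if len(standards) < 3:
        raise InputError("SEC calibration needs at least 3 standards")
    x = np.array([s.Rh_A for s in standards])
    y = np.array([_y_of_kav(kav(s.Ve_mL, Vo, Vt), log_base) for s in standards])
    res = stats.linregress(x, y)
    if abs(res.slope) < 1e-12:
        raise FitError("SEC calibration slope is zero; cannot invert for Rh")
    return SECCalibration(
        Vo=Vo,
        Vt=Vt,
        standards=standards,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        log_base=log_base,
    )


def estimate_rh(cal: SECCalibration, Ve: float) -> float:
    """Invert the calibration line: Rh (Å) of a species eluting at Ve (mL)."""
    y = _y_of_kav(kav(Ve, cal.Vo, cal.Vt), cal.log_base)
    return (y - cal.intercept) / cal.slope


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def read_kinetics_csv(path) -> dict[str, KineticsDataset]:
    """Read ``substrate,S_uM,v_per_s,replicate`` CSV into per-substrate datasets."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"kinetics CSV not found: {path}")
    df = pd.read_csv(path)
    needed = {"substrate", "S_uM", "v_per_s"}
    if not needed.issubset(df.columns):
        raise InputError(f"{path}: expected columns {sorted(needed)}")
    return {
        str(sub): KineticsDataset(substrate=str(sub), points=grp.reset_index(drop=True))
        for sub, grp in df.groupby("substrate")
    }


def read_sec_csv(path) -> list[SECStandard]:
    """Read ``name,Rh_A,Ve_mL`` CSV of SEC standards."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"SEC CSV not found: {path}")
    df = pd.read_csv(path)
    needed = {"name", "Rh_A", "Ve_mL"}
    if not needed.issubset(df.columns):
        raise InputError(f"{path}: expected columns {sorted(needed)}")
    return [
        SECStandard(str(row["name"]), float(row["Rh_A"]), float(row["Ve_mL"]))
        for _, row in df.iterrows()
    ]
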