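"""Published reference values for rabbit ALOX15 and its interface mutants.

Two small tables of literature values ship with the package:

* steady-state kinetic constants (kcat, KM with standard errors) of
  wild-type rabbit ALOX15 and the His585Glu / Trp181Glu interface mutants
  for linoleic (LA) and arachidonic (AA) acid oxygenation;
* trajectory-averaged reactive-geometry statistics (mean cofactor
  distances, well-oriented and pre-catalytic percentages) for the wild-type
  and Trp181Glu enzyme-substrate complexes.

They serve as worked-example inputs for the arithmetic layers of the
package (catalytic efficiencies, fold changes, distance shifts) — the
underlying trajectories and absorbance traces are not redistributable.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .reactive import GeometrySummary

__all__ = ["load_reference_kinetics", "load_reference_geometry"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("loxmd.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_kinetics() -> pd.DataFrame:
    """Kinetic constants per (enzyme, substrate); kcat s^-1, KM µM."""
    return _read("alox15_kinetics_reference.csv")


def load_reference_geometry() -> dict[tuple[str, str], GeometrySummary]:
    """Reactive-geometry summaries keyed by (system, substrate).

    ``n_frames`` is 0: the per-frame data behind these averages is not
    available, only the published summary statistics.
    """
    df = _read("alox15_reactive_geometry_reference.csv")
    out = {}
    for _, row in df.iterrows():
        out[(row["system"], row["substrate"])] = GeometrySummary(
            n_frames=0,
            mean_d_C_OH=float(row["mean_d_C_OH"]),
            mean_d_HproS_OH=float(row["mean_d_HproS_OH"]),
            mean_d_HproR_OH=float(row["mean_d_HproR_OH"]),
            pct_well_oriented=float(row["pct_well_oriented"]),
            pct_precatalytic=float(row["pct_precatalytic"]),
        )
    return out
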