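"""End-to-end pipeline: config-driven runs producing a report bundle.

A :class:`RunConfig` names one or more systems (trajectory + selection
config), the analyses to run, and parameter overrides.  :func:`run_pipeline`
executes the requested analyses per system and writes a deterministic bundle
of CSV/JSON outputs plus a manifest recording parameters and input hashes,
so a bundle can always be reproduced from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .clustering import CLUSTER_CUTOFF_A, cluster_frames, extract_centroid, pairwise_rmsd
from .errors import ConfigError, InputError
from .kinetics import (
    MichaelisMenten,
    calibrate_sec,
    estimate_rh,
    read_kinetics_csv,
    read_sec_csv,
)
from .metrics import (
    HBOND_ANGLE_CUTOFF_DEG,
    HBOND_DISTANCE_CUTOFF_A,
    assign_helix,
    contact_distance_series,
    detect_anchor_hbonds,
)
from .reactive import (
    PRECATALYTIC_CUTOFF_A,
    classify,
    compare_summaries,
    compute_reactive_distances,
    distances_frame,
    summarize,
)
from .trajectory import Trajectory, load_selection_config, read_frame_table, read_multimodel_pdb, write_pdb
from .util import round_half_up

__all__ = ["RunConfig", "load_run_config", "run_pipeline", "render_geometry_table", "render_kinetics_table"]

ANALYSES = ("geometry", "cluster", "hbonds", "helix", "contacts", "kinetics", "sec")


class _SystemConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    trajectory: str
    topology: str
    format: str = "auto"  # auto | pdb | table


class _GeometryParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cutoff: float = PRECATALYTIC_CUTOFF_A
    discard_ns: float = 0.0


class _ClusterParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cutoff: float = CLUSTER_CUTOFF_A


class _HBondParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    d_cutoff: float = HBOND_DISTANCE_CUTOFF_A
    angle_cutoff: float = HBOND_ANGLE_CUTOFF_DEG


class _KineticsParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    csv: str


class _SECParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    csv: str
    Vo: float
    Vt: float
    query_Ve: list[float] = []


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML/JSON; unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    output_dir: str
    analyses: list[str]
    systems: list[_SystemConfig] = []
    compare: Optional[tuple[str, str]] = None  # (system a, reference b)
    seed: int = 0
    geometry: _GeometryParams = _GeometryParams()
    cluster: _ClusterParams = _ClusterParams()
    hbonds: _HBondParams = _HBondParams()
    kinetics: Optional[_KineticsParams] = None
    sec: Optional[_SECParams] = None

    def validate_semantics(self) -> None:
        if not self.analyses:
            raise ConfigError("no analyses requested")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ConfigError(f"unknown analyses: {sorted(unknown)}")
        traj_analyses = set(self.analyses) & {"geometry", "cluster", "hbonds", "helix", "contacts"}
        if traj_analyses and not self.systems:
            raise ConfigError(f"analyses {sorted(traj_analyses)} need at least one system")
        if "kinetics" in self.analyses and self.kinetics is None:
            raise ConfigError("kinetics analysis requested but no kinetics.csv configured")
        if "sec" in self.analyses and self.sec is None:
            raise ConfigError("sec analysis requested but no sec parameters configured")
        names = [s.name for s in self.systems]
        if len(set(names)) != len(names):
            raise ConfigError("system names must be unique")
        if self.compare is not None:
            for n in self.compare:
                if n not in names:
                    raise ConfigError(f"compare references unknown system {n!r}")


def load_run_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"run config not found: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    try:
        config = RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    config.validate_semantics()
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_trajectory(traj_path, topology_path, fmt: str = "auto") -> Trajectory:
    traj_path = Path(traj_path)
    config = load_selection_config(topology_path)
    if fmt == "auto":
        fmt = "pdb" if traj_path.suffix.lower() in (".pdb", ".ent") else "table"
    if fmt == "pdb":
        return read_multimodel_pdb(traj_path, config)
    if fmt == "table":
        return read_frame_table(traj_path, config)
    raise ConfigError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# per-analysis runners
# ---------------------------------------------------------------------------


def _run_geometry(traj, params: _GeometryParams, outdir: Path, name: str) -> dict:
    if params.discard_ns > 0:
        traj = traj.discard_before(params.discard_ns)
    rds = compute_reactive_distances(traj)
    classes = classify(rds, cutoff=params.cutoff)
    summary = summarize(rds, classes)
    df = distances_frame(rds, classes)
    df.to_csv(outdir / f"{name}_geometry_frames.csv", index=False)
    summary_dict = summary.as_dict()
    with open(outdir / f"{name}_geometry_summary.json", "w") as fh:
        json.dump(summary_dict, fh, indent=2, sort_keys=True)
    return {"summary": summary, "summary_dict": summary_dict}


def _run_cluster(traj, params: _ClusterParams, outdir: Path, name: str) -> dict:
    sel = traj.topology.substrate_heavy_atoms
    if not sel:
        raise InputError(f"system {name}: no substrate_heavy_atoms selection for clustering")
    matrix = pairwise_rmsd(traj, sel)
    result = cluster_frames(matrix, cutoff=params.cutoff)
    centroid = extract_centroid(traj, matrix, result)
    pd.DataFrame(
        {"frame": [f.index for f in traj.frames], "cluster": result.labels}
    ).to_csv(outdir / f"{name}_cluster_labels.csv", index=False)
    info = {
        "sizes": result.sizes.tolist(),
        "n_clusters": int(result.n_clusters),
        "centroid_frame": int(centroid.index),
        "cutoff_A": params.cutoff,
    }
    with open(outdir / f"{name}_clusters.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
    pos = [i for i, f in enumerate(traj.frames) if f.index == centroid.index]
    write_pdb(traj, outdir / f"{name}_centroid.pdb", frame_indices=pos)
    return info


def _run_hbonds(traj, params: _HBondParams, outdir: Path, name: str) -> dict:
    events, occupancy = detect_anchor_hbonds(
        traj, d_cutoff=params.d_cutoff, angle_cutoff=params.angle_cutoff
    )
    pd.DataFrame(
        [
            {
                "frame": e.frame_index,
                "donor": repr(e.donor),
                "hydrogen": repr(e.hydrogen),
                "acceptor": repr(e.acceptor),
                "d_H_A": e.d_H_A,
                "angle_DHA": e.angle_DHA,
            }
            for e in events
        ]
    ).to_csv(outdir / f"{name}_hbond_events.csv", index=False)
    occ = {f"{d!r}->{a!r}": v for (d, a), v in sorted(occupancy.items(), key=lambda kv: repr(kv[0]))}
    with open(outdir / f"{name}_hbond_occupancy.json", "w") as fh:
        json.dump(occ, fh, indent=2, sort_keys=True)
    return {"n_events": len(events), "occupancy": occ}


def _run_helix(traj, outdir: Path, name: str) -> dict:
    segments = traj.topology.helix_segments
    if not segments:
        raise InputError(f"system {name}: no helix_segments in topology")
    rows, result = [], {}
    for segname, segment in sorted(segments.items()):
        metrics = assign_helix(traj, segment)
        for m in metrics:
            rows.append(
                {
                    "frame": m.frame_index,
                    "segment": segname,
                    "longest_run": m.longest_run,
                    "n_turns": m.n_turns,
                    "flags": "".join("H" if f else "-" for f in m.helical_flags),
                }
            )
        result[segname] = {
            "final_longest_run": metrics[-1].longest_run,
            "final_n_turns": metrics[-1].n_turns,
        }
    pd.DataFrame(rows).to_csv(outdir / f"{name}_helix.csv", index=False)
    with open(outdir / f"{name}_helix.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    return result


def _run_contacts(traj, outdir: Path, name: str) -> dict:
    pairs = traj.topology.interface_pairs
    if not pairs:
        raise InputError(f"system {name}: no interface_pairs in topology")
    rows, result = [], {}
    for a, b in pairs:
        series = contact_distance_series(traj, (a, b))
        key = f"{a!r}--{b!r}"
        for f, d in zip(traj.frames, series.distances):
            rows.append({"frame": f.index, "time_ns": f.time_ns, "pair": key, "distance_A": d})
        result[key] = {"mean_A": series.mean, "sd_A": series.sd}
    pd.DataFrame(rows).to_csv(outdir / f"{name}_contacts.csv", index=False)
    with open(outdir / f"{name}_contacts.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    return result


def _run_kinetics(params: _KineticsParams, outdir: Path) -> pd.DataFrame:
    datasets = read_kinetics_csv(params.csv)
    rows = []
    for sub in sorted(datasets):
        fit = MichaelisMenten.from_dataset(datasets[sub]).fit()
        rows.append(
            {
                "substrate": sub,
                "kcat_per_s": fit.kcat,
                "se_kcat": fit.se_kcat,
                "KM_uM": fit.KM,
                "se_KM": fit.se_KM,
                "efficiency_per_s_per_uM": fit.efficiency,
                "rss": fit.rss,
                "n_points": fit.n_points,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "kinetics_fits.csv", index=False)
    return df


def _run_sec(params: _SECParams, outdir: Path) -> dict:
    standards = read_sec_csv(params.csv)
    cal = calibrate_sec(standards, Vo=params.Vo, Vt=params.Vt)
    result = {
        "Vo_mL": cal.Vo,
        "Vt_mL": cal.Vt,
        "slope": cal.slope,
        "intercept": cal.intercept,
        "r_squared": cal.r_squared,
        "estimates": [
            {"Ve_mL": ve, "Rh_A": estimate_rh(cal, ve)} for ve in params.query_Ve
        ],
    }
    with open(outdir / "sec_calibration.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    return result


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Run all requested analyses; return the bundle summary dict."""
    config.validate_semantics()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"systems": {}, "version": __version__}
    inputs: dict[str, str] = {}

    geometry_summaries = {}
    for system in config.systems:
        traj = load_trajectory(system.trajectory, system.topology, system.format)
        inputs[system.trajectory] = _sha256(Path(system.trajectory))
        inputs[system.topology] = _sha256(Path(system.topology))
        sysout: dict = {}
        if "geometry" in config.analyses:
            res = _run_geometry(traj, config.geometry, outdir, system.name)
            geometry_summaries[system.name] = res["summary"]
            sysout["geometry"] = res["summary_dict"]
        if "cluster" in config.analyses:
            sysout["cluster"] = _run_cluster(traj, config.cluster, outdir, system.name)
        if "hbonds" in config.analyses:
            sysout["hbonds"] = _run_hbonds(traj, config.hbonds, outdir, system.name)
        if "helix" in config.analyses:
            sysout["helix"] = _run_helix(traj, outdir, system.name)
        if "contacts" in config.analyses:
            sysout["contacts"] = _run_contacts(traj, outdir, system.name)
        bundle["systems"][system.name] = sysout

    if config.compare is not None and "geometry" in config.analyses:
        a, b = config.compare
        comparison = compare_summaries(geometry_summaries[a], geometry_summaries[b])
        bundle["comparison"] = {
            "system": a,
            "reference": b,
            "fold_precatalytic": comparison.fold_precatalytic,
            "fold_well_oriented": comparison.fold_well_oriented,
            "delta_mean_d_C_OH_A": comparison.delta_mean_d_C_OH,
            "display": {
                "fold_precatalytic": comparison.display_fold_precatalytic,
                "fold_well_oriented": comparison.display_fold_well_oriented,
                "delta_mean_d_C_OH_A": comparison.display_delta_mean_d_C_OH,
            },
        }
        with open(outdir / "comparison.json", "w") as fh:
            json.dump(bundle["comparison"], fh, indent=2, sort_keys=True)

    if "kinetics" in config.analyses:
        df = _run_kinetics(config.kinetics, outdir)
        inputs[config.kinetics.csv] = _sha256(Path(config.kinetics.csv))
        bundle["kinetics"] = df.to_dict(orient="records")
    if "sec" in config.analyses:
        bundle["sec"] = _run_sec(config.sec, outdir)
        inputs[config.sec.csv] = _sha256(Path(config.sec.csv))

    manifest = {
        "loxmd_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "input_sha256": inputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, default=float)
    return bundle


# ---------------------------------------------------------------------------
# report rendering (all rounding happens here, never upstream)
# ---------------------------------------------------------------------------


def _fmt(x, ndigits) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "n/a"
    return f"{round_half_up(float(x), ndigits):.{ndigits}f}"


def render_geometry_table(summaries: dict) -> str:
    """Reactive-geometry summary table: distances and percentages, 2 decimals."""
    header = (
        f"{'System':20s} {'d(C-OH)(Å)':>11s} {'d(HproS-OH)(Å)':>15s} "
        f"{'d(HproR-OH)(Å)':>15s} {'Well-Oriented(%)':>17s} {'Pre-Catalytic(%)':>17s}"
    )
    lines = [header]
    for name, s in summaries.items():
        if s is None or getattr(s, "n_frames", 0) == 0 and np.isnan(getattr(s, "mean_d_C_OH", np.nan)):
            lines.append(f"{name:20s} {'n/a':>11s} {'n/a':>15s} {'n/a':>15s} {'n/a':>17s} {'n/a':>17s}")
            continue
        lines.append(
            f"{name:20s} {_fmt(s.mean_d_C_OH, 2):>11s} {_fmt(s.mean_d_HproS_OH, 2):>15s} "
            f"{_fmt(s.mean_d_HproR_OH, 2):>15s} {_fmt(s.pct_well_oriented, 2):>17s} "
            f"{_fmt(s.pct_precatalytic, 2):>17s}"
        )
    return "\n".join(lines)


def render_kinetics_table(fits: pd.DataFrame) -> str:
    """Kinetics table: kcat, KM (2 decimals) and kcat/KM (1 decimal)."""
    lines = [f"{'Substrate':12s} {'kcat(s-1)':>12s} {'KM(uM)':>10s} {'kcat/KM(s-1 uM-1)':>18s}"]
    for _, row in fits.iterrows():
        lines.append(
            f"{str(row['substrate']):12s} {_fmt(row['kcat_per_s'], 2):>12s} "
            f"{_fmt(row['KM_uM'], 2):>10s} {_fmt(row['efficiency_per_s_per_uM'], 1):>18s}"
        )
    return "\n".join(lines)
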