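"""Trajectory containers, atom addressing, and trajectory I/O.

A :class:`Trajectory` couples an ordered list of coordinate frames (Å) with a
:class:`TopologySpec` that names the atoms every downstream analysis needs:
the hydroxide oxygen of the Fe(III)-OH cofactor, the bisallylic carbon of the
bound fatty acid and its two prochiral hydrogens, substrate heavy atoms,
carboxylate H-bond anchors, helix segments and inter-monomer contact pairs.

Atoms are always addressed by ``(monomer, residue_number, atom_name)`` so that
selections are independent of the order in which atom records appear in the
input file.  Residue numbers are taken verbatim from the input (rabbit ALOX15
numbering of PDB entry 2P0M in the intended application); no renumbering is
performed.  Coordinates are ångström throughout the package.

Two interchangeable on-disk formats are supported: standard multi-model PDB
(one MODEL per frame, parsed with MDAnalysis) and a plain TSV frame table with
columns ``frame  time_ns  monomer  resnum  atom  x  y  z``, which round-trips
coordinates exactly and is the native output of the synthetic generators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import (
    ConfigError,
    EmptyTrajectoryError,
    InputError,
    RaggedFrameError,
    UnresolvedAddressError,
)

__all__ = [
    "Address",
    "AtomRecord",
    "HelixSegment",
    "TopologySpec",
    "Frame",
    "Trajectory",
    "AUTO",
    "load_selection_config",
    "read_multimodel_pdb",
    "read_frame_table",
    "write_frame_table",
    "write_pdb",
]

#: Sentinel for prochiral hydrogens to be assigned geometrically.
AUTO = "AUTO"

#: Frame spacing (ns) assumed when the input format carries no time axis.
DEFAULT_DT_NS = 0.1


class Address(NamedTuple):
    """Atom address: ``(monomer, residue_number, atom_name)``."""

    monomer: str
    resnum: int
    atom: str

    def __repr__(self) -> str:  # keep error messages compact and verbatim
        return f"{self.monomer}/{self.resnum}/{self.atom}"


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    monomer_id: str

    @property
    def address(self) -> Address:
        return Address(self.monomer_id, self.residue_number, self.name)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass(frozen=True)
class HelixSegment:
    """Residue range (inclusive) of a named helix on one monomer."""

    name: str
    monomer: str
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ConfigError(f"helix segment {self.name}: end < start")

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)


# ---------------------------------------------------------------------------
# selection config (file-facing schema)
# ---------------------------------------------------------------------------


class _AddressModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    monomer: str
    resnum: int
    atom: str

    def to_address(self) -> Address:
        return Address(self.monomer, self.resnum, self.atom)


class _DonorModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    donor: _AddressModel
    hydrogen: _AddressModel


class _HelixModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    monomer: str
    start: int
    end: int


class SelectionConfig(BaseModel):
    """Schema-validated topology/selection configuration (YAML or JSON).

    Every field is optional: an analysis fails with a clear error only when a
    selection it actually needs is absent.  Unknown keys are rejected.
    """

    model_config = ConfigDict(extra="forbid")

    cofactor_oxygen: Optional[_AddressModel] = None
    iron: Optional[_AddressModel] = None
    reactive_carbon: Optional[_AddressModel] = None
    h_proS: Optional[Union[_AddressModel, str]] = None
    h_proR: Optional[Union[_AddressModel, str]] = None
    substrate_heavy_atoms: list[_AddressModel] = []
    carboxylate_oxygens: list[_AddressModel] = []
    anchor_donors: list[_DonorModel] = []
    anchor_acceptors: list[_AddressModel] = []
    helix_segments: dict[str, _HelixModel] = {}
    interface_pairs: list[tuple[_AddressModel, _AddressModel]] = []
    branch_priority: Optional[_AddressModel] = None
    bonds: list[tuple[_AddressModel, _AddressModel]] = []


def load_selection_config(path) -> SelectionConfig:
    """Load and validate a YAML/JSON selection config."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"selection config not found: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    try:
        return SelectionConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _opt_addr(m: Optional[Union[_AddressModel, str]]):
    if m is None:
        return None
    if isinstance(m, str):
        if m != AUTO:
            raise ConfigError(f"prochiral hydrogen must be an address or {AUTO!r}, got {m!r}")
        return AUTO
    return m.to_address()


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


@dataclass
class TopologySpec:
    """Atom list plus the named selections used by the analyses.

    Selections are stored as :class:`Address` values; :meth:`index` resolves an
    address to its 0-based position in ``atoms`` and raises
    :class:`UnresolvedAddressError` (quoting the address verbatim) when no atom
    matches.
    """

    atoms: list[AtomRecord]
    bonds: frozenset = frozenset()  # frozenset of frozenset({i, j}) index pairs
    cofactor_oxygen: Optional[Address] = None
    iron: Optional[Address] = None
    reactive_carbon: Optional[Address] = None
    h_proS: Optional[Union[Address, str]] = None
    h_proR: Optional[Union[Address, str]] = None
    substrate_heavy_atoms: list[Address] = field(default_factory=list)
    carboxylate_oxygens: list[Address] = field(default_factory=list)
    anchor_donors: list[tuple[Address, Address]] = field(default_factory=list)
    anchor_acceptors: list[Address] = field(default_factory=list)
    helix_segments: dict[str, HelixSegment] = field(default_factory=dict)
    interface_pairs: list[tuple[Address, Address]] = field(default_factory=list)
    branch_priority: Optional[Address] = None

    def __post_init__(self):
        self._index: dict[Address, int] = {}
        serials = set()
        for i, a in enumerate(self.atoms):
            if a.serial in serials:
                raise ConfigError(f"duplicate atom serial {a.serial}")
            serials.add(a.serial)
            if a.address in self._index:
                raise ConfigError(f"duplicate atom address {a.address!r}")
            self._index[a.address] = i
        if (
            self.h_proS not in (None, AUTO)
            and self.h_proR not in (None, AUTO)
            and self.h_proS == self.h_proR
        ):
            raise ConfigError("h_proS and h_proR must name different atoms")
        self._validate_selections()

    # -- resolution ---------------------------------------------------------

    def index(self, address: Address) -> int:
        try:
            return self._index[Address(*address)]
        except KeyError:
            raise UnresolvedAddressError(Address(*address)) from None

    def indices(self, addresses: Iterable[Address]) -> np.ndarray:
        return np.array([self.index(a) for a in addresses], dtype=int)

    def _validate_selections(self) -> None:
        for addr in (
            self.cofactor_oxygen,
            self.iron,
            self.reactive_carbon,
            self.branch_priority,
        ):
            if addr is not None:
                self.index(addr)
        for h in (self.h_proS, self.h_proR):
            if h is not None and h != AUTO:
                self.index(h)
        for addr in (
            list(self.substrate_heavy_atoms)
            + list(self.carboxylate_oxygens)
            + list(self.anchor_acceptors)
        ):
            self.index(addr)
        for d, h in self.anchor_donors:
            self.index(d)
            self.index(h)
        for a, b in self.interface_pairs:
            self.index(a)
            self.index(b)

    # -- connectivity -------------------------------------------------------

    def neighbors(self, i: int) -> list[int]:
        """Indices bonded to atom ``i`` (sorted)."""
        out = []
        for pair in self.bonds:
            if i in pair and len(pair) == 2:
                (j,) = set(pair) - {i}
                out.append(j)
        return sorted(out)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_selection_dict(self) -> dict:
        """Selection config dict (inverse of :meth:`from_config`), YAML-ready."""

        def addr(a):
            if a is None or a == AUTO:
                return a
            return {"monomer": a.monomer, "resnum": int(a.resnum), "atom": a.atom}

        out: dict = {}
        for key in ("cofactor_oxygen", "iron", "reactive_carbon", "h_proS", "h_proR",
                    "branch_priority"):
            val = getattr(self, key)
            if val is not None:
                out[key] = addr(val)
        for key in ("substrate_heavy_atoms", "carboxylate_oxygens", "anchor_acceptors"):
            vals = getattr(self, key)
            if vals:
                out[key] = [addr(a) for a in vals]
        if self.anchor_donors:
            out["anchor_donors"] = [
                {"donor": addr(d), "hydrogen": addr(h)} for d, h in self.anchor_donors
            ]
        if self.helix_segments:
            out["helix_segments"] = {
                name: {"monomer": seg.monomer, "start": seg.start, "end": seg.end}
                for name, seg in self.helix_segments.items()
            }
        if self.interface_pairs:
            out["interface_pairs"] = [[addr(a), addr(b)] for a, b in self.interface_pairs]
        if self.bonds:
            addr_of = [a.address for a in self.atoms]
            out["bonds"] = [
                [addr(addr_of[i]), addr(addr_of[j])]
                for i, j in (sorted(p) for p in self.bonds if len(p) == 2)
            ]
        return out

    def find_residue_atom(self, monomer: str, resnum: int, name: str) -> Optional[int]:
        return self._index.get(Address(monomer, resnum, name))

    @classmethod
    def from_config(
        cls, atoms: list[AtomRecord], config: Optional[SelectionConfig],
        bonds: Iterable[tuple[int, int]] = (),
    ) -> "TopologySpec":
        bondset = frozenset(frozenset(p) for p in bonds)
        if config is None:
            return cls(atoms=atoms, bonds=bondset)
        # explicit bond addresses in the config extend whatever the file gave
        idx = {a.address: i for i, a in enumerate(atoms)}

        def _resolve(m: _AddressModel) -> int:
            addr = m.to_address()
            if addr not in idx:
                raise UnresolvedAddressError(addr)
            return idx[addr]

        extra = frozenset(frozenset((_resolve(a), _resolve(b))) for a, b in config.bonds)
        return cls(
            atoms=atoms,
            bonds=bondset | extra,
            cofactor_oxygen=_opt_addr(config.cofactor_oxygen),
            iron=_opt_addr(config.iron),
            reactive_carbon=_opt_addr(config.reactive_carbon),
            h_proS=_opt_addr(config.h_proS),
            h_proR=_opt_addr(config.h_proR),
            substrate_heavy_atoms=[m.to_address() for m in config.substrate_heavy_atoms],
            carboxylate_oxygens=[m.to_address() for m in config.carboxylate_oxygens],
            anchor_donors=[
                (d.donor.to_address(), d.hydrogen.to_address()) for d in config.anchor_donors
            ],
            anchor_acceptors=[m.to_address() for m in config.anchor_acceptors],
            helix_segments={
                name: HelixSegment(name, h.monomer, h.start, h.end)
                for name, h in config.helix_segments.items()
            },
            interface_pairs=[(a.to_address(), b.to_address()) for a, b in config.interface_pairs],
            branch_priority=_opt_addr(config.branch_priority),
        )


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    index: int
    time_ns: float
    coords: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError(f"frame {self.index}: coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise InputError(f"frame {self.index}: non-finite coordinates")
        if self.index < 0 or self.time_ns < 0:
            raise InputError(f"frame {self.index}: negative index or time")


@dataclass
class Trajectory:
    topology: TopologySpec
    frames: list[Frame]

    def __post_init__(self):
        n = self.topology.n_atoms
        prev_idx, prev_t = -1, -math.inf
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise RaggedFrameError(
                    f"frame {f.index} has {f.coords.shape[0]} atoms, topology has {n}"
                )
            if f.index <= prev_idx:
                raise InputError("frame indices must be strictly increasing")
            if f.time_ns < prev_t:
                raise InputError("frame times must be non-decreasing")
            prev_idx, prev_t = f.index, f.time_ns

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def coords(self) -> np.ndarray:
        """All coordinates, shape ``(n_frames, n_atoms, 3)``."""
        return np.stack([f.coords for f in self.frames])

    @property
    def times_ns(self) -> np.ndarray:
        return np.array([f.time_ns for f in self.frames])

    def subset_frames(self, indices: Sequence[int]) -> "Trajectory":
        keep = [self.frames[i] for i in indices]
        return Trajectory(self.topology, keep)

    def discard_before(self, t_ns: float) -> "Trajectory":
        """Drop frames with ``time_ns < t_ns`` (equilibration window)."""
        keep = [f for f in self.frames if f.time_ns >= t_ns]
        if not keep:
            raise EmptyTrajectoryError(f"no frames at or after {t_ns} ns")
        return Trajectory(self.topology, keep)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TWO_LETTER = {"FE", "CL", "BR", "NA", "MG", "ZN", "MN", "CA", "SE"}


def _guess_element(name: str) -> str:
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2].capitalize()
    return stripped[:1] if stripped else "X"


def _as_config(topology_config) -> Optional[SelectionConfig]:
    if topology_config is None or isinstance(topology_config, SelectionConfig):
        return topology_config
    return load_selection_config(topology_config)


def read_multimodel_pdb(path, topology_config=None, dt_ns: float = DEFAULT_DT_NS) -> Trajectory:
    """Read a multi-model PDB file (one MODEL per frame).

    ``topology_config`` may be a :class:`SelectionConfig`, a path to a YAML or
    JSON file, or None.  CONECT records (and explicit ``bonds`` in the config)
    supply the connectivity needed for geometric prochiral assignment.  The
    PDB format carries no time axis; frames are spaced ``dt_ns`` apart.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"trajectory file not found: {path}")
    config = _as_config(topology_config)
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # inconsistent models, unparsable records
            raise InputError(f"cannot read PDB {path}: {exc}") from exc
        try:
            elements = [str(e).capitalize() for e in u.atoms.elements]
        except Exception:
            elements = [_guess_element(n) for n in u.atoms.names]
        try:
            chains = list(u.atoms.chainIDs)
        except Exception:
            chains = list(u.atoms.segids)
        atoms = [
            AtomRecord(
                serial=int(u.atoms.ids[i]),
                name=str(u.atoms.names[i]),
                element=elements[i],
                residue_name=str(u.atoms.resnames[i]),
                residue_number=int(u.atoms.resids[i]),
                monomer_id=str(chains[i]).strip() or "A",
            )
            for i in range(len(u.atoms))
        ]
        bonds = []
        if hasattr(u, "bonds"):
            bonds = [(int(b[0].index), int(b[1].index)) for b in u.bonds]
        topology = TopologySpec.from_config(atoms, config, bonds=bonds)
        frames = [
            Frame(index=i, time_ns=i * dt_ns, coords=u.atoms.positions.astype(float).copy())
            for i, _ in enumerate(u.trajectory)
        ]
    if not frames:
        raise EmptyTrajectoryError(f"{path} contains no frames")
    return Trajectory(topology, frames)


TABLE_COLUMNS = ["frame", "time_ns", "monomer", "resnum", "atom", "x", "y", "z"]


def read_frame_table(path, topology_config=None) -> Trajectory:
    """Read the TSV frame-table format (exact-precision exchange format)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"frame table not found: {path}")
    config = _as_config(topology_config)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype={"monomer": str, "atom": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise EmptyTrajectoryError(f"{path} is empty") from None
    if list(df.columns) != TABLE_COLUMNS:
        raise InputError(f"{path}: expected columns {TABLE_COLUMNS}, got {list(df.columns)}")
    if df.empty:
        raise EmptyTrajectoryError(f"{path} contains no frames")
    for col in ("x", "y", "z", "time_ns"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise InputError(f"{path}: non-numeric values in column {col!r}")
    first = df[df["frame"] == df["frame"].iloc[0]]
    keys = list(zip(first["monomer"], first["resnum"], first["atom"]))
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=str(atom),
            element=_guess_element(str(atom)),
            residue_name="UNK",
            residue_number=int(resnum),
            monomer_id=str(mono),
        )
        for i, (mono, resnum, atom) in enumerate(keys)
    ]
    topology = TopologySpec.from_config(atoms, config)
    frames = []
    for fidx, grp in df.groupby("frame", sort=True):
        gkeys = list(zip(grp["monomer"], grp["resnum"], grp["atom"]))
        if len(gkeys) != len(keys) or set(gkeys) != set(keys):
            raise RaggedFrameError(f"frame {fidx}: atom list differs from the first frame")
        # reorder rows to topology order regardless of on-disk row order
        order = {k: i for i, k in enumerate(gkeys)}
        xyz = grp[["x", "y", "z"]].to_numpy(dtype=float)
        coords = np.empty_like(xyz)
        for i, k in enumerate(keys):
            coords[i] = xyz[order[(k[0], k[1], k[2])]]
        times = grp["time_ns"].to_numpy()
        frames.append(Frame(index=int(fidx), time_ns=float(times[0]), coords=coords))
    return Trajectory(topology, frames)


def write_frame_table(traj: Trajectory, path) -> None:
    """Write the TSV frame table; floats use ``repr`` so read() is lossless."""
    path = Path(path)
    rows = []
    for f in traj.frames:
        for a, (x, y, z) in zip(traj.topology.atoms, f.coords):
            rows.append(
                (f.index, repr(float(f.time_ns)), a.monomer_id, a.residue_number,
                 a.name, repr(float(x)), repr(float(y)), repr(float(z)))
            )
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_pdb(traj: Trajectory, path, frame_indices: Optional[Sequence[int]] = None) -> None:
    """Write frames as a (multi-)model PDB via MDAnalysis."""
    import MDAnalysis as mda

    top = traj.topology
    n = top.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n), trajectory=True)
    u.add_TopologyAttr("names", [a.name for a in top.atoms])
    u.add_TopologyAttr("resnames", [a.residue_name for a in top.atoms])
    u.add_TopologyAttr("resids", [a.residue_number for a in top.atoms])
    u.add_TopologyAttr("chainIDs", [a.monomer_id[:1] for a in top.atoms])
    u.add_TopologyAttr("elements", [a.element for a in top.atoms])
    frames = traj.frames if frame_indices is None else [traj.frames[i] for i in frame_indices]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=len(frames) > 1) as w:
            for f in frames:
                u.atoms.positions = f.coords
                w.write(u.atoms)
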