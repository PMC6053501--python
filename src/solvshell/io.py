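"""Domain types and file I/O.

The package works on a light-weight in-memory :class:`Trajectory` (frames x
atoms x 3 coordinates in nm, per-frame orthorhombic box, frame spacing in
ps) plus an atom table that distinguishes protein, solvent and ion
molecules.  Standard structure/trajectory formats (PDB, GRO, XTC, DCD) are
read through MDAnalysis; a plain-text fixture format is provided so tests
and examples never need binary readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Trajectory",
    "RegionSpec",
    "min_image_displacement",
    "read_system",
    "write_fixture",
    "read_fixture",
    "write_table",
    "read_table",
    "load_region_map",
    "DEFAULT_CLASSIFICATION",
]

MOL_CLASSES = ("protein", "solvent", "ion")

_AMINO3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL HSD HSE HSP HID HIE HIP CYX ASH GLH LYN"
).split()
_WATERS = "SOL HOH WAT TIP3 TIP4 SPC SPCE W".split()
_IONS = "NA CL K MG CA ZN NA+ CL- SOD CLA".split()

#: default resname -> mol_class mapping covering standard residue names
DEFAULT_CLASSIFICATION: dict[str, str] = (
    {r: "protein" for r in _AMINO3}
    | {r: "solvent" for r in _WATERS}
    | {r: "ion" for r in _IONS}
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the system.

    ``index`` is 0-based and unique; ``resid`` is 1-based as in PDB;
    ``mol_id`` is unique per molecule and ``mol_class`` is one of
    ``{"protein", "solvent", "ion"}`` and fixed across frames.
    """

    index: int
    name: str
    element: str
    resid: int
    resname: str
    mol_id: int
    mol_class: str

    def __post_init__(self) -> None:
        if self.resid < 1:
            raise ValueError(f"resid must be >= 1, got {self.resid}")
        if self.mol_class not in MOL_CLASSES:
            raise ValueError(f"unknown mol_class {self.mol_class!r}")


@dataclass
class Trajectory:
    """Coordinates (nm) for a fixed atom set over equally spaced frames."""

    atoms: list[AtomRecord]
    coords: np.ndarray          # (n_frames, n_atoms, 3), nm
    box: np.ndarray             # (n_frames, 3) orthorhombic edges, nm
    dt: float                   # ps
    origin_time: float = 0.0    # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms but the atom "
                f"table has {len(self.atoms)}"
            )
        if self.box.shape != (self.coords.shape[0], 3):
            raise ValueError("box must have shape (frames, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if not np.all(self.box > 0):
            raise ValueError("box edges must be positive")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise ValueError("atom indices are not unique")

    # -- convenience ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.origin_time + self.dt * np.arange(self.n_frames)

    def atom_indices(self, mol_class: str) -> np.ndarray:
        return np.array(
            [a.index for a in self.atoms if a.mol_class == mol_class], dtype=int
        )

    def molecules(self, mol_class: str | None = None) -> dict[int, np.ndarray]:
        """mol_id -> atom-index array, optionally restricted to one class."""
        out: dict[int, list[int]] = {}
        for a in self.atoms:
            if mol_class is None or a.mol_class == mol_class:
                out.setdefault(a.mol_id, []).append(a.index)
        return {m: np.array(ix, dtype=int) for m, ix in sorted(out.items())}

    def region_atom_indices(
        self, region: "RegionSpec", scope: str = "all"
    ) -> np.ndarray:
        """Protein atom indices inside a region's residue ranges.

        ``scope`` is ``"all"`` or ``"side_chain"`` (backbone names
        excluded) or ``"c_alpha"``.
        """
        backbone = {"N", "CA", "C", "O", "OXT", "H", "HA", "HN", "H1", "H2", "H3"}
        picked = []
        for a in self.atoms:
            if a.mol_class != "protein":
                continue
            if not any(lo <= a.resid <= hi for lo, hi in region.resid_ranges):
                continue
            if scope == "side_chain" and a.name in backbone:
                continue
            if scope == "c_alpha" and a.name != "CA":
                continue
            picked.append(a.index)
        return np.array(picked, dtype=int)

    def unwrapped(self, atom_indices: Sequence[int] | None = None) -> np.ndarray:
        """Coordinates with periodic jumps removed, per atom.

        Valid when no atom moves more than half a box edge per frame, which
        holds for solvent diffusion at MD frame spacings.
        """
        ix = (
            np.arange(self.n_atoms)
            if atom_indices is None
            else np.asarray(atom_indices, dtype=int)
        )
        x = self.coords[:, ix, :]
        out = np.empty_like(x)
        out[0] = x[0]
        for f in range(1, self.n_frames):
            d = x[f] - x[f - 1]
            d = _wrap(d, self.box[f])
            out[f] = out[f - 1] + d
        return out


@dataclass(frozen=True)
class RegionSpec:
    """A named protein region: residue ranges plus class/exposure labels."""

    name: str
    klass: str                          # helix / sheet / loop / connector
    resid_ranges: tuple[tuple[int, int], ...]
    exposure: str = "Ext"               # Ext / Int / Int-Ext
    cutoff_nm: float | None = None

    def __post_init__(self) -> None:
        if self.klass not in ("helix", "sheet", "loop", "connector"):
            raise ValueError(f"unknown region class {self.klass!r}")
        if self.exposure not in ("Ext", "Int", "Int-Ext"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        ranges = tuple(tuple(r) for r in self.resid_ranges)
        if not ranges:
            raise ValueError("resid_ranges must be non-empty")
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"range start {lo} > end {hi}")
        object.__setattr__(self, "resid_ranges", ranges)

    def contains(self, resid: int) -> bool:
        return any(lo <= resid <= hi for lo, hi in self.resid_ranges)


# ---------------------------------------------------------------------------
# minimum-image arithmetic
# ---------------------------------------------------------------------------

def _wrap(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement components into (-box/2, box/2]."""
    half = 0.5 * np.asarray(box)
    w = np.mod(np.asarray(d) + half, box) - half     # [-box/2, box/2)
    # map the closed lower edge onto the open upper edge
    return np.where(w <= -half, w + box, w)


def min_image_displacement(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Minimum-image displacement ``b - a`` under an orthorhombic box.

    Each component of the result lies in ``(-box_i/2, box_i/2]``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite positions passed to min_image_displacement")
    if not np.all(box > 0):
        raise ValueError("box edges must be positive")
    return _wrap(b - a, box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = min_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# fixture text format
# ---------------------------------------------------------------------------

_FIXTURE_MAGIC = "SOLVSHELL-TRAJ 1"


def write_fixture(traj: Trajectory, path: str | Path) -> Path:
    """Write the plain-text fixture trajectory format.

    Floats are written with ``repr`` so a read-back reproduces the stored
    values bitwise.
    """
    path = Path(path)
    lines = [_FIXTURE_MAGIC]
    lines.append(f"natoms {traj.n_atoms}")
    lines.append(f"nframes {traj.n_frames}")
    lines.append(f"dt {traj.dt!r}")
    lines.append(f"origin_time {traj.origin_time!r}")
    lines.append("atoms index name element resid resname mol_id mol_class")
    for a in traj.atoms:
        lines.append(
            f"{a.index} {a.name} {a.element} {a.resid} {a.resname} "
            f"{a.mol_id} {a.mol_class}"
        )
    for f in range(traj.n_frames):
        bx = [float(v) for v in traj.box[f]]
        lines.append(f"frame {f} box {bx[0]!r} {bx[1]!r} {bx[2]!r}")
        for x, y, z in traj.coords[f]:
            lines.append(f"{float(x)!r} {float(y)!r} {float(z)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_fixture(path: str | Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _FIXTURE_MAGIC:
        raise ValueError(f"{path} is not a fixture trajectory")
    it = iter(lines[1:])
    natoms = int(next(it).split()[1])
    nframes = int(next(it).split()[1])
    dt = float(next(it).split()[1])
    origin_time = float(next(it).split()[1])
    header = next(it)
    if not header.startswith("atoms"):
        raise ValueError("malformed fixture: missing atom table")
    atoms = []
    for _ in range(natoms):
        tok = next(it).split()
        atoms.append(
            AtomRecord(
                index=int(tok[0]), name=tok[1], element=tok[2],
                resid=int(tok[3]), resname=tok[4],
                mol_id=int(tok[5]), mol_class=tok[6],
            )
        )
    coords = np.empty((nframes, natoms, 3))
    box = np.empty((nframes, 3))
    for f in range(nframes):
        tok = next(it).split()
        box[f] = [float(tok[3]), float(tok[4]), float(tok[5])]
        for i in range(natoms):
            coords[f, i] = [float(v) for v in next(it).split()]
    return Trajectory(atoms=atoms, coords=coords, box=box, dt=dt,
                      origin_time=origin_time)


# ---------------------------------------------------------------------------
# standard formats through MDAnalysis
# ---------------------------------------------------------------------------

def _classify(resname: str, rules: Mapping[str, str]) -> str:
    if resname in rules:
        return rules[resname]
    raise ValueError(
        f"no mol_class rule for resname {resname!r}; "
        "extend classification_rules"
    )


def read_system(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    classification_rules: Mapping[str, str] | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Read a topology (PDB/GRO) plus optional trajectory into nm/ps units.

    ``classification_rules`` maps resname to mol_class and is merged over
    the built-in defaults for standard residue/water/ion names.  ``dt``
    overrides the frame spacing when the source format carries none.
    """
    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(str(topology_path))
    if str(topology_path).endswith((".fixt", ".fixture", ".sstraj")):
        return read_fixture(topology_path)
    if trajectory_path is not None and str(trajectory_path).endswith(
        (".fixt", ".fixture", ".sstraj")
    ):
        return read_fixture(trajectory_path)

    import MDAnalysis as mda

    rules = dict(DEFAULT_CLASSIFICATION)
    if classification_rules:
        rules.update(classification_rules)

    if trajectory_path is None:
        u = mda.Universe(str(topology_path))
    else:
        trajectory_path = Path(trajectory_path)
        if not trajectory_path.exists():
            raise FileNotFoundError(str(trajectory_path))
        try:
            u = mda.Universe(str(topology_path), str(trajectory_path))
        except ValueError as e:
            raise ValueError(
                f"topology/trajectory atom-count mismatch: {e}"
            ) from e

    atoms = []
    mol_id = -1
    prev_key: tuple | None = None
    for a in u.atoms:
        resname = str(a.resname).strip()
        klass = _classify(resname, rules)
        # protein residues merge into one molecule per contiguous stretch;
        # every solvent / ion residue is its own molecule
        key = ("protein",) if klass == "protein" else ("res", a.resid, a.segid)
        if key != prev_key:
            if not (klass == "protein" and prev_key == ("protein",)):
                mol_id += 1
            prev_key = key
        try:
            element = str(a.element).strip()
        except Exception:
            element = str(a.name).strip()[:1]
        atoms.append(
            AtomRecord(
                index=int(a.index), name=str(a.name).strip(), element=element,
                resid=int(a.resid), resname=resname,
                mol_id=mol_id, mol_class=klass,
            )
        )

    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(u.atoms), 3))
    box = np.empty((n_frames, 3))
    times = []
    for f, ts in enumerate(u.trajectory):
        dims = ts.dimensions
        if dims is None or np.all(dims[:3] == 0):
            # unboxed structure files: use a generous bounding box
            span = u.atoms.positions.max(0) - u.atoms.positions.min(0)
            dims = np.concatenate([span + 100.0, [90.0, 90.0, 90.0]])
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise ValueError(
                "only orthorhombic boxes are supported; got box angles "
                f"{tuple(dims[3:6])}"
            )
        coords[f] = u.atoms.positions / 10.0          # A -> nm
        box[f] = dims[:3] / 10.0
        times.append(float(ts.time))
    if dt is None:
        dt_file = times[1] - times[0] if n_frames > 1 else 0.0
        dt = dt_file if dt_file > 0 else 1.0
    return Trajectory(atoms=atoms, coords=coords, box=box, dt=float(dt))


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(records, path: str | Path, format: str | None = None) -> Path:
    """Write tabular results to CSV or JSON, lossless for numeric fields.

    ``records`` may be a DataFrame or a list of dicts; it must be non-empty.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if df.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        path.write_text(df.to_json(orient="records", double_precision=15))
    else:
        raise ValueError(f"unknown table format {fmt!r}")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# region maps
# ---------------------------------------------------------------------------

def load_region_map(source: str | Path | Mapping) -> dict[str, RegionSpec]:
    """Load a named region map from YAML (or a parsed mapping).

    Expected layout::

        regions:
          alpha5: {class: helix, residues: [[142, 146]], exposure: Ext}
          loop23: {class: loop, residues: [[23, 32]], cutoff_nm: 0.5}
    """
    if isinstance(source, (str, Path)):
        import yaml

        data = yaml.safe_load(Path(source).read_text())
    else:
        data = dict(source)
    entries = data.get("regions", data)
    out: dict[str, RegionSpec] = {}
    for name, cfg in entries.items():
        if name in out:
            raise ValueError(f"duplicate region name {name!r}")
        out[name] = RegionSpec(
            name=name,
            klass=cfg.get("class", cfg.get("klass", "helix")),
            resid_ranges=tuple(tuple(r) for r in cfg["residues"]),
            exposure=cfg.get("exposure", "Ext"),
            cutoff_nm=cfg.get("cutoff_nm"),
        )
    return out
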