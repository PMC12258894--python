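"""Domain containers and file I/O shared by all analysis stages.

Containers
----------
:class:`AtomTable`
    Per-atom identity (names, residue ids, chains, elements) plus partial
    charges and van der Waals radii.  Charges and radii are never inferred
    from a force field; they come from a sidecar CSV table
    (``residue_name, atom_name, charge, radius``) with coarse defaults for
    standard amino acids shipped with the package.
:class:`Trajectory`
    Frames of coordinates with per-frame periodic box edges.
:class:`ScalarGrid`
    A regular 3D scalar field (charge density, electrostatic potential)
    serialisable to the OpenDX dialect used by common visualisation tools.
:class:`SelectionSpec`
    A small declarative atom-selection language (residue ranges, atom
    names, chains, residue names), resolved deterministically against an
    :class:`AtomTable`.

Conventions: coordinates in Angstrom, z is the membrane normal, residue
numbering is taken from the source PDB without renumbering.  OpenDX values
are stored z-fastest.
"""

from __future__ import annotations

import io
import os
import re
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
from gridData import Grid as _DXGrid

__all__ = [
    "AtomTable",
    "Trajectory",
    "ScalarGrid",
    "SelectionSpec",
    "load_structure",
    "write_structure",
    "load_trajectory",
    "write_trajectory",
    "read_grid",
    "write_grid",
    "select_atoms",
    "load_charge_table",
    "DEFAULT_CHARGE_TABLE_PATH",
]

DEFAULT_CHARGE_TABLE_PATH = Path(__file__).parent / "data" / "charges_default.csv"

# fallback vdW radii by element (A); used when the sidecar table has no entry
_ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "K": 2.75, "NA": 2.27, "CL": 1.75, "CA": 2.31, "MG": 1.73, "ZN": 1.39,
}
_DEFAULT_RADIUS = 1.50


@dataclass
class AtomTable:
    """Columnar per-atom metadata; rows are in file order."""

    atom_id: np.ndarray
    atom_name: np.ndarray
    residue_id: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray
    partial_charge: np.ndarray
    vdw_radius: np.ndarray

    def __post_init__(self):
        self.atom_id = np.asarray(self.atom_id, dtype=int)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.residue_id = np.asarray(self.residue_id, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.partial_charge = np.asarray(self.partial_charge, dtype=float)
        self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
        if len(np.unique(self.atom_id)) != len(self.atom_id):
            raise ValueError("atom_ids must be unique")
        if np.any(self.vdw_radius < 0):
            raise ValueError("vdw_radius must be non-negative")

    def __len__(self):
        return len(self.atom_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "atom_id": self.atom_id,
                "atom_name": self.atom_name,
                "residue_id": self.residue_id,
                "residue_name": self.residue_name,
                "chain_id": self.chain_id,
                "element": self.element,
                "partial_charge": self.partial_charge,
                "vdw_radius": self.vdw_radius,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AtomTable":
        return cls(**{k: df[k].to_numpy() for k in df.columns})

    def index_of(self, residue_id: int, atom_name: str, chain_id: str | None = None):
        """Return the (sorted) indices of atoms matching (residue_id, atom_name).

        Deterministic: indices are returned in file order.
        """
        mask = (self.residue_id == residue_id) & (self.atom_name == atom_name)
        if chain_id is not None:
            mask &= self.chain_id == chain_id
        return np.flatnonzero(mask)

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask over atoms excluding hydrogens."""
        return np.array([e != "H" for e in self.element], dtype=bool)


@dataclass
class Trajectory:
    """Coordinate frames (n_frames, n_atoms, 3) in A with per-frame box edges."""

    coordinates: np.ndarray
    box: np.ndarray  # (n_frames, 3) orthorhombic edges Lx, Ly, Lz in A
    timestep: float = 0.0  # ns between stored frames

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ScalarGrid:
    """Regular 3D scalar field on an orthogonal grid with uniform spacing."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    periodic: bool = False
    units_label: str = ""

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")

    @property
    def shape(self):
        return self.values.shape

    def axes(self):
        """Node coordinates along x, y, z."""
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.values.shape[i])
            for i in range(3)
        )


# ---------------------------------------------------------------------------
# selection language
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")


@dataclass(frozen=True)
class SelectionSpec:
    """Comma-separated conjunction of clauses, each ``keyword value...``.

    Keywords: ``resid``/``residue``/``residues`` (integers or ranges like
    ``109-135``), ``name``, ``resname``, ``chain``, ``element``.  Values in
    one clause are OR-ed; clauses are AND-ed.  Example::

        "residues 109-135, name CA"
    """

    expression: str

    def resolve(self, atoms: AtomTable, strict: bool = False) -> np.ndarray:
        mask = np.ones(len(atoms), dtype=bool)
        expr = self.expression.strip()
        if not expr:
            return np.arange(len(atoms))
        for clause in expr.split(","):
            tokens = clause.split()
            if not tokens:
                continue
            key, values = tokens[0].lower(), tokens[1:]
            if not values:
                raise ValueError(f"selection clause {clause!r} has no values")
            if key in ("resid", "residue", "residues"):
                sub = np.zeros(len(atoms), dtype=bool)
                for v in values:
                    m = _RANGE_RE.match(v)
                    if m:
                        lo, hi = int(m.group(1)), int(m.group(2))
                        sub |= (atoms.residue_id >= lo) & (atoms.residue_id <= hi)
                    else:
                        sub |= atoms.residue_id == int(v)
            elif key in ("name", "resname", "chain", "element"):
                col = {
                    "name": atoms.atom_name,
                    "resname": atoms.residue_name,
                    "chain": atoms.chain_id,
                    "element": atoms.element,
                }[key]
                if strict:
                    known = set(col.tolist())
                    unknown = [v for v in values if v not in known]
                    if unknown:
                        raise ValueError(
                            f"selection {key} value(s) {unknown} not present in table"
                        )
                sub = np.isin(col, values)
            else:
                raise ValueError(f"unknown selection keyword {key!r}")
            mask &= sub
        return np.flatnonzero(mask)


def select_atoms(atoms: AtomTable, spec: SelectionSpec | str, strict: bool = False):
    """Resolve a selection to sorted unique atom indices (pure function)."""
    if isinstance(spec, str):
        spec = SelectionSpec(spec)
    return spec.resolve(atoms, strict=strict)


# ---------------------------------------------------------------------------
# charge/radius sidecar table
# ---------------------------------------------------------------------------

def load_charge_table(path=None) -> pd.DataFrame:
    """Load the (residue_name, atom_name) -> (charge, radius) sidecar CSV.

    A residue_name of ``*`` acts as a wildcard matched after exact rows.
    """
    path = Path(path) if path is not None else DEFAULT_CHARGE_TABLE_PATH
    df = pd.read_csv(path, comment="#")
    required = {"residue_name", "atom_name", "charge", "radius"}
    if not required.issubset(df.columns):
        raise ValueError(f"charge table must have columns {sorted(required)}")
    return df


def _assign_charges_radii(atoms_df: pd.DataFrame, table: pd.DataFrame):
    exact = {
        (r, a): (q, rad)
        for r, a, q, rad in zip(
            table.residue_name, table.atom_name, table.charge, table.radius
        )
        if r != "*"
    }
    wild = {
        a: (q, rad)
        for r, a, q, rad in zip(
            table.residue_name, table.atom_name, table.charge, table.radius
        )
        if r == "*"
    }
    charges = np.zeros(len(atoms_df))
    radii = np.zeros(len(atoms_df))
    for i, (rn, an, el) in enumerate(
        zip(atoms_df["residue_name"], atoms_df["atom_name"], atoms_df["element"])
    ):
        hit = exact.get((rn, an)) or wild.get(an)
        if hit is not None:
            charges[i], radii[i] = hit
        else:
            charges[i] = 0.0
            radii[i] = _ELEMENT_RADII.get(str(el).upper(), _DEFAULT_RADIUS)
    return charges, radii


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


# ---------------------------------------------------------------------------
# structure I/O (PDB)
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    raise ValueError(
                        f"{path}: malformed coordinate record at line {lineno}"
                    ) from None


def load_structure(path, charge_table=None):
    """Read a PDB file into an (:class:`AtomTable`, coordinates) pair.

    ``charge_table`` is a DataFrame or CSV path of per-(residue, atom)
    charges/radii; defaults to the table shipped with the package.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    ag = u.atoms
    names = ag.names.astype(object)
    try:
        elements = ag.elements.astype(object)
    except (mda.exceptions.NoDataError, AttributeError):
        elements = np.array([_guess_element(n) for n in names], dtype=object)
    try:
        chains = ag.chainIDs.astype(object)
    except (mda.exceptions.NoDataError, AttributeError):
        chains = ag.segids.astype(object)
    df = pd.DataFrame(
        {
            "atom_id": ag.ids,
            "atom_name": names,
            "residue_id": ag.resids,
            "residue_name": ag.resnames.astype(object),
            "chain_id": chains,
            "element": elements,
        }
    )
    if charge_table is None or isinstance(charge_table, (str, Path)):
        charge_table = load_charge_table(charge_table)
    charges, radii = _assign_charges_radii(df, charge_table)
    df["partial_charge"] = charges
    df["vdw_radius"] = radii
    return AtomTable.from_dataframe(df), ag.positions.astype(float)


def write_structure(path, atoms: AtomTable, coords: np.ndarray):
    """Write an AtomTable plus one coordinate frame as PDB."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(atoms), 3):
        raise ValueError("coordinate shape does not match atom table")
    res_keys = list(dict.fromkeys(zip(atoms.chain_id, atoms.residue_id)))
    res_index = {k: i for i, k in enumerate(res_keys)}
    atom_resindex = np.array(
        [res_index[(c, r)] for c, r in zip(atoms.chain_id, atoms.residue_id)]
    )
    seg_keys = list(dict.fromkeys(k[0] for k in res_keys))
    seg_index = {k: i for i, k in enumerate(seg_keys)}
    res_segindex = np.array([seg_index[k[0]] for k in res_keys])
    u = mda.Universe.empty(
        n_atoms=len(atoms),
        n_residues=len(res_keys),
        n_segments=len(seg_keys),
        atom_resindex=atom_resindex,
        residue_segindex=res_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms.atom_name.astype(str))
    u.add_TopologyAttr("elements", atoms.element.astype(str))
    u.add_TopologyAttr("resids", np.array([k[1] for k in res_keys]))
    u.add_TopologyAttr(
        "resnames",
        np.array(
            [atoms.residue_name[atom_resindex == i][0] for i in range(len(res_keys))],
            dtype=str,
        ),
    )
    u.add_TopologyAttr("chainIDs", atoms.chain_id.astype(str))
    u.add_TopologyAttr("segids", np.array(seg_keys, dtype=str))
    u.atoms.positions = coords
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# trajectory I/O (DCD/XTC via MDAnalysis)
# ---------------------------------------------------------------------------

def _dcd_declared_frames(path: Path) -> int | None:
    """Number of frames declared in a DCD header (None for other formats)."""
    with open(path, "rb") as fh:
        head = fh.read(12)
        if len(head) < 12 or head[4:8] != b"CORD":
            return None
        return struct.unpack("<i", head[8:12])[0]


def load_trajectory(path, atoms: AtomTable) -> Trajectory:
    """Read a DCD or XTC trajectory for a known AtomTable.

    A frame count shorter than the DCD header declares (a truncated file)
    raises instead of silently returning fewer frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    u = mda.Universe.empty(n_atoms=len(atoms), trajectory=True)
    try:
        u.load_new(str(path))
    except (ValueError, IOError) as err:
        raise ValueError(
            f"could not read trajectory {path} for {len(atoms)} atoms: {err}"
        ) from err
    if u.trajectory.n_atoms != len(atoms):
        raise ValueError(
            f"trajectory has {u.trajectory.n_atoms} atoms, "
            f"atom table has {len(atoms)}"
        )
    if path.suffix.lower() == ".dcd":
        declared = _dcd_declared_frames(path)
        if declared is not None and u.trajectory.n_frames < declared:
            raise ValueError(
                f"truncated trajectory {path}: header declares {declared} frames, "
                f"file holds {u.trajectory.n_frames}"
            )
    coords = np.empty((u.trajectory.n_frames, len(atoms), 3))
    box = np.empty((u.trajectory.n_frames, 3))
    for i, ts in enumerate(u.trajectory):
        coords[i] = ts.positions
        box[i] = ts.dimensions[:3] if ts.dimensions is not None else np.nan
    dt_ns = (u.trajectory.dt or 0.0) / 1000.0  # MDAnalysis dt is in ps
    return Trajectory(coordinates=coords, box=box, timestep=dt_ns)


def write_trajectory(path, traj: Trajectory):
    """Write a Trajectory as DCD (or XTC, by extension)."""
    path = str(path)
    u = mda.Universe.empty(n_atoms=traj.n_atoms, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=traj.n_atoms) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[i]
                u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# grid I/O (OpenDX)
# ---------------------------------------------------------------------------

def write_grid(grid: ScalarGrid, path):
    """Serialise a ScalarGrid to OpenDX (values z-fastest)."""
    g = _DXGrid(grid.values, origin=grid.origin, delta=grid.spacing)
    g.export(str(path), file_format="dx")


def read_grid(path) -> ScalarGrid:
    """Read an OpenDX scalar grid written by this package or PMEPot-style tools."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        g = _DXGrid(str(path))
    except Exception as err:  # gridData raises a mix of types on bad input
        raise ValueError(f"{path} is not a readable OpenDX grid: {err}") from err
    delta = np.asarray(g.delta)
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0]):
        raise ValueError("only uniform grid spacing is supported")
    return ScalarGrid(
        origin=np.asarray(g.origin, dtype=float),
        spacing=float(delta[0]),
        values=np.asarray(g.grid, dtype=float),
    )
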