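"""Structural time-series descriptors for voltage-gating trajectories.

Covers the quantities typically tracked while a channel activates under
voltage: z-displacement of charged-group proxy atoms (guanidinium CZ for
Arg, sidechain carboxyl carbon for Asp/Glu), helix tilt angles against the
membrane normal, helix center-of-mass displacement, backbone RMSD after
least-squares superposition, pore hydration counts, a simplified axial
pore-radius profile, ion permeation events through the filter slab, the
single-channel conductance they imply, and block-averaged statistics.

Conventions: z is the membrane normal; tilt is the angle between the helix
principal axis (oriented N-terminus to C-terminus) and +z, folded into
[0, 90] degrees; displacements are relative to a reference frame with no
whole-protein drift correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core_io import AtomTable, SelectionSpec, Trajectory, select_atoms
from .units import ELEMENTARY_CHARGE_C, R_KCAL_MOL_K

__all__ = [
    "HelixDefinition",
    "ChargeGroupProxy",
    "PoreRegion",
    "PermeationRecord",
    "charge_z_displacement",
    "helix_tilt",
    "helix_com_displacement",
    "rmsd",
    "pore_water_count",
    "pore_radius_profile",
    "detect_permeations",
    "conductance",
    "block_average",
    "running_average",
    "boltzmann_inversion_2d",
    "DEFAULT_BK_HELICES",
]

#: transmembrane helix ranges of the Core-MT BK channel construct
DEFAULT_BK_HELICES = {
    "S1": (109, 135),
    "S2": (148, 170),
    "S3": (181, 199),
    "S4": (205, 225),
    "S5": (230, 259),
    "S6": (313, 324),  # below the glycine hinge
}

#: sidechain charged-group proxy atom by residue name
PROXY_ATOM_BY_RESNAME = {"ARG": "CZ", "ASP": "CG", "GLU": "CD", "LYS": "NZ"}


@dataclass
class HelixDefinition:
    name: str
    first_residue: int
    last_residue: int
    atom_subset: str = "name CA"

    def __post_init__(self):
        if self.first_residue > self.last_residue:
            raise ValueError("first_residue must be <= last_residue")
        if self.last_residue - self.first_residue + 1 < 4:
            raise ValueError("need >= 4 residues for a defined helix axis")

    def selection(self, chain: str | None = None) -> SelectionSpec:
        expr = f"residues {self.first_residue}-{self.last_residue}, {self.atom_subset}"
        if chain is not None:
            expr += f", chain {chain}"
        return SelectionSpec(expr)


@dataclass
class ChargeGroupProxy:
    residue_id: int
    proxy_atom: str
    chain_id: str | None = None

    @classmethod
    def for_residue(cls, atoms: AtomTable, residue_id: int, chain_id=None):
        """Pick the conventional proxy atom from the residue name."""
        mask = atoms.residue_id == residue_id
        if chain_id is not None:
            mask &= atoms.chain_id == chain_id
        names = set(atoms.residue_name[mask].tolist())
        if not names:
            raise ValueError(f"residue {residue_id} not found")
        resname = sorted(names)[0]
        proxy = PROXY_ATOM_BY_RESNAME.get(resname)
        if proxy is None:
            raise ValueError(f"no charged-group proxy for residue {resname} {residue_id}")
        return cls(residue_id, proxy, chain_id)

    def resolve(self, atoms: AtomTable) -> int:
        idx = atoms.index_of(self.residue_id, self.proxy_atom, self.chain_id)
        if len(idx) == 0:
            raise ValueError(
                f"proxy atom {self.proxy_atom} missing for residue {self.residue_id}"
            )
        return int(idx[0])


@dataclass
class PoreRegion:
    """Axial slab below the selectivity filter with a radial cutoff.

    Bounds are either fixed z values (float) or selections whose per-frame
    center-of-mass z defines the bound.  The pore axis (x, y) is the
    center of the ``axis_spec`` selection per frame, or a fixed pair.
    """

    lower: float | str | SelectionSpec
    upper: float | str | SelectionSpec
    radial_cutoff: float = 8.0
    axis: tuple | str | SelectionSpec = (0.0, 0.0)

    def _bound(self, bound, frame_coords, atoms):
        if isinstance(bound, (int, float)):
            return float(bound)
        idx = select_atoms(atoms, bound)
        if len(idx) == 0:
            raise ValueError("pore-bound selection matched no atoms")
        return float(frame_coords[idx, 2].mean())

    def bounds(self, frame_coords, atoms):
        lo = self._bound(self.lower, frame_coords, atoms)
        hi = self._bound(self.upper, frame_coords, atoms)
        return lo, hi

    def axis_xy(self, frame_coords, atoms):
        if isinstance(self.axis, tuple):
            return np.asarray(self.axis, dtype=float)
        idx = select_atoms(atoms, self.axis)
        if len(idx) == 0:
            raise ValueError("pore-axis selection matched no atoms")
        return frame_coords[idx, :2].mean(axis=0)


@dataclass
class PermeationRecord:
    ion_id: int
    frame_of_entry: int
    frame_of_exit: int
    direction: str  # "up" or "down"

    def __post_init__(self):
        if self.frame_of_entry >= self.frame_of_exit:
            raise ValueError("entry must precede exit")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


# ---------------------------------------------------------------------------
# displacement / tilt / rmsd
# ---------------------------------------------------------------------------

def running_average(series: np.ndarray, window: int = 100) -> np.ndarray:
    """Centered moving average with edge shrinkage (window clipped at ends)."""
    series = np.asarray(series, dtype=float)
    if window <= 1:
        return series.copy()
    half = window // 2
    out = np.empty_like(series)
    for i in range(len(series)):
        lo, hi = max(0, i - half), min(len(series), i + half + 1)
        out[i] = series[lo:hi].mean()
    return out


def charge_z_displacement(
    traj: Trajectory, proxies, atoms: AtomTable, reference_frame: int = 0,
    window: int | None = None, average_chains: bool = False,
) -> pd.DataFrame:
    """z(proxy, t) - z(proxy, reference) for each charged-group proxy.

    Returns a tidy frame (frame, residue_id, chain, dz).  With
    ``average_chains`` the per-subunit series sharing a residue_id are
    averaged (the four-subunit average of a homotetramer); ``window``
    applies a centered running average per series.
    """
    records = []
    for proxy in proxies:
        i = proxy.resolve(atoms)
        z = traj.coordinates[:, i, 2]
        dz = z - z[reference_frame]
        if window:
            dz = running_average(dz, window)
        for f, v in enumerate(dz):
            records.append(
                (f, proxy.residue_id, atoms.chain_id[i], float(v))
            )
    df = pd.DataFrame(records, columns=["frame", "residue_id", "chain", "dz"])
    if average_chains:
        df = (
            df.groupby(["frame", "residue_id"], as_index=False)["dz"].mean()
        )
    return df


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Dominant right-singular vector of centered coordinates, oriented N->C."""
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-10 or len(coords) < 4:
        raise ValueError("degenerate axis: need >= 4 non-collinear atoms")
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis


def helix_tilt(traj: Trajectory, helix: HelixDefinition, atoms: AtomTable,
               chain: str | None = None) -> np.ndarray:
    """Per-frame angle (deg) between the helix principal axis and +z, in [0, 90]."""
    idx = select_atoms(atoms, helix.selection(chain))
    if len(idx) < 4:
        raise ValueError(f"helix {helix.name}: fewer than 4 axis atoms selected")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        axis = _principal_axis(traj.coordinates[f, idx])
        cosang = abs(np.clip(axis[2] / np.linalg.norm(axis), -1.0, 1.0))
        out[f] = np.degrees(np.arccos(cosang))
    return out


def helix_com_displacement(
    traj: Trajectory, helix: HelixDefinition, atoms: AtomTable,
    reference_frame: int = 0, chain: str | None = None,
) -> np.ndarray:
    """Center-of-mass displacement (n_frames, 3) of a helix selection
    relative to its position in ``reference_frame`` (unit masses)."""
    idx = select_atoms(atoms, helix.selection(chain))
    if len(idx) == 0:
        raise ValueError(f"helix {helix.name}: empty selection")
    com = traj.coordinates[:, idx, :].mean(axis=1)
    return com - com[reference_frame]


def boltzmann_inversion_2d(xy: np.ndarray, bins: int = 40, temperature: float = 300.0):
    """Convert (x, y) samples into a free-energy surface -RT ln P(x, y).

    Returns ``(free_energy kcal/mol, x_edges, y_edges)``; empty bins are
    +inf.  The minimum is shifted to zero.
    """
    h, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins)
    p = h / h.sum()
    with np.errstate(divide="ignore"):
        g = -R_KCAL_MOL_K * temperature * np.log(p)
    g -= g[np.isfinite(g)].min()
    return g, xe, ye


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation+translation of mobile onto target (least squares)."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot, mc, tc


def rmsd(
    traj: Trajectory, reference: np.ndarray, atoms: AtomTable,
    selection, superpose_selection=None,
) -> np.ndarray:
    """Per-frame RMSD to reference coordinates after least-squares
    superposition on ``superpose_selection`` (defaults to ``selection``).

    ``reference`` holds full-system coordinates for one frame.  Passing
    ``superpose_selection=None`` with ``superpose=False`` semantics is not
    offered; to skip superposition superpose on the same rigid selection.
    """
    sel = select_atoms(atoms, selection)
    sup = select_atoms(atoms, superpose_selection) if superpose_selection is not None else sel
    if len(sel) == 0 or len(sup) == 0:
        raise ValueError("empty selection")
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] != traj.n_atoms:
        raise ValueError(
            f"reference has {reference.shape[0]} atoms, trajectory {traj.n_atoms}"
        )
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        rot, mc, tc = _kabsch(frame[sup], reference[sup])
        moved = rot.apply(frame[sel] - mc) + tc
        out[f] = np.sqrt(np.mean(np.sum((moved - reference[sel]) ** 2, axis=1)))
    return out


# ---------------------------------------------------------------------------
# pore hydration and profile
# ---------------------------------------------------------------------------

def pore_water_count(
    traj: Trajectory, region: PoreRegion, atoms: AtomTable, water_selection,
) -> np.ndarray:
    """Per-frame count of water oxygens inside the pore slab and radius."""
    widx = select_atoms(atoms, water_selection)
    out = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        lo, hi = region.bounds(frame, atoms)
        if lo >= hi:
            raise ValueError(f"inverted pore bounds at frame {f}: {lo} >= {hi}")
        axis = region.axis_xy(frame, atoms)
        w = frame[widx]
        inside = (w[:, 2] >= lo) & (w[:, 2] < hi)
        r = np.linalg.norm(w[:, :2] - axis, axis=1)
        out[f] = int(np.sum(inside & (r <= region.radial_cutoff)))
    return out


def pore_radius_profile(
    frame_coords: np.ndarray, atoms: AtomTable, axis_xy=(0.0, 0.0),
    z_range=(-25.0, 25.0), dz: float = 1.0, slab_half: float | None = None,
    max_probe: float = 15.0, selection=None,
) -> pd.DataFrame:
    """Simplified axial pore profile: per z-slice, the smallest clearance
    between the pore axis and any nearby atom surface.

    radius(z) = min over atoms with |z_atom - z| <= slab_half of
    (distance from axis to atom center - vdw_radius), clamped at >= 0.
    Slices with no nearby atoms report ``max_probe`` and are flagged.
    """
    if slab_half is None:
        slab_half = dz
    idx = (select_atoms(atoms, selection) if selection is not None
           else np.arange(len(atoms)))
    pts = frame_coords[idx]
    radii = atoms.vdw_radius[idx]
    axis = np.asarray(axis_xy, dtype=float)
    zs = np.arange(z_range[0], z_range[1] + 1e-9, dz)
    rows = []
    rad_xy = np.linalg.norm(pts[:, :2] - axis, axis=1)
    for z in zs:
        near = np.abs(pts[:, 2] - z) <= slab_half
        if not near.any():
            rows.append((z, max_probe, True))
            continue
        clearance = np.min(rad_xy[near] - radii[near])
        rows.append((z, max(clearance, 0.0), False))
    return pd.DataFrame(rows, columns=["z", "radius", "flagged"])


# ---------------------------------------------------------------------------
# permeation and conductance
# ---------------------------------------------------------------------------

def detect_permeations(tracks, slab_lower: float, slab_upper: float):
    """Count full slab traversals per ion track.

    ``tracks``: iterable of ``(ion_id, times, z_values)`` (times may be
    None).  An event is recorded only when an ion enters through one
    boundary and exits through the other without first leaving back through
    the entry boundary; partial crossings never count.  A step that jumps
    across the whole slab counts as an instantaneous traversal.
    """
    if slab_lower >= slab_upper:
        raise ValueError("slab_lower must be < slab_upper")

    def region(z):
        if z < slab_lower:
            return -1
        if z >= slab_upper:
            return +1
        return 0

    events = []
    for ion_id, _times, z in tracks:
        z = np.asarray(z, dtype=float)
        prev = region(z[0])
        entry_side = None
        entry_frame = None
        for f in range(1, len(z)):
            cur = region(z[f])
            if cur == prev:
                continue
            if prev != 0 and cur == 0:
                entry_side, entry_frame = prev, f
            elif prev == 0 and cur != 0:
                if entry_side is not None and cur == -entry_side:
                    events.append(PermeationRecord(
                        ion_id, entry_frame, f, "up" if cur == 1 else "down"))
                entry_side, entry_frame = None, None
            elif prev != 0 and cur == -prev:  # jumped straight across
                events.append(PermeationRecord(
                    ion_id, f - 1 if f > 0 else 0, f, "up" if cur == 1 else "down"))
                entry_side, entry_frame = None, None
            prev = cur
        # leftover entry without exit: no event
    return events


def conductance(events, voltage: float, duration: float) -> float:
    """Single-channel conductance g = N_net e / (V T) in siemens.

    ``events`` may be a PermeationRecord list or an ``(n_up, n_down)``
    pair; ``voltage`` in volts, ``duration`` in seconds.  Net events are
    counted along the field (up minus down for positive voltage).
    """
    if voltage == 0:
        raise ValueError("conductance undefined at zero voltage")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(events, tuple):
        n_up, n_down = events
    else:
        n_up = sum(1 for e in events if e.direction == "up")
        n_down = sum(1 for e in events if e.direction == "down")
    n_net = (n_up - n_down) * np.sign(voltage)
    return float(n_net * ELEMENTARY_CHARGE_C / (abs(voltage) * duration))


def block_average(series, n_blocks: int):
    """Mean of block means and its standard error sd(blocks)/sqrt(n_blocks).

    The series is split into ``n_blocks`` contiguous equal blocks (a
    remainder shorter than a block is dropped from the end).
    """
    series = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(series) < n_blocks:
        raise ValueError(f"series of length {len(series)} < {n_blocks} blocks")
    m = len(series) // n_blocks
    means = series[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1) / np.sqrt(n_blocks))
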