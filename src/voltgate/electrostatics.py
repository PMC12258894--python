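"""Smeared-charge Poisson electrostatics with an imposed membrane voltage.

Each atomic charge q_i is represented by a spherical Gaussian density

    rho_i(r) = q_i (beta / sqrt(pi))^3 exp(-beta^2 |r - r_i|^2)

with inverse width beta (default 0.25 1/A) accumulated on a regular grid
(default 1 A spacing) with periodic wrapping.  The potential solves the
periodic Poisson equation in Gaussian units,

    laplacian(phi) = -4 pi rho,

spectrally (FFT), with the k = 0 mode set to zero: the grid mean of phi is
the gauge, and any net charge is implicitly neutralised by a uniform
background (flagged in the result).  Internally phi is in e/A; multiply by
14.39964 for volts.  A membrane voltage V enters as a separate linear ramp
with total drop V across the box along z (E = V / L_z); by default the
potential is higher on the low-z (intracellular) face for positive V, so a
positive V is depolarising.  The ramp is stored separately so the pure
charge-generated field remains inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core_io import AtomTable, ScalarGrid, Trajectory
from .units import COULOMB_V_A_PER_E

__all__ = [
    "SmearingSpec",
    "PotentialGrid",
    "smear_charges",
    "solve_poisson",
    "add_external_field",
    "average_potential",
    "plane_slice",
    "potential_at",
    "external_ramp",
]

#: relative density below which the Gaussian tail is truncated
_TRUNCATION = 1e-10


@dataclass
class SmearingSpec:
    beta: float = 0.25  # 1/A, inverse Gaussian width
    grid_spacing: float = 1.0  # A

    def __post_init__(self):
        if self.beta <= 0 or self.grid_spacing <= 0:
            raise ValueError("beta and grid_spacing must be positive")

    @property
    def cutoff(self) -> float:
        """Radius beyond which the Gaussian is below _TRUNCATION of its peak."""
        return np.sqrt(-np.log(_TRUNCATION)) / self.beta


@dataclass
class PotentialGrid(ScalarGrid):
    """Electrostatic potential (e/A internally) with optional external ramp."""

    applied_voltage: float = 0.0  # V
    box_lz: float = 0.0  # A
    neutralized: bool = False
    depolarizing_positive: bool = True

    def external_ramp_at(self, z):
        """External potential (volts) at height z for the stored voltage."""
        return external_ramp(
            np.asarray(z, dtype=float), self.applied_voltage,
            self.origin[2], self.box_lz, self.depolarizing_positive,
        )

    def total_values(self, unit: str = "e/A") -> np.ndarray:
        """Charge-generated field plus external ramp, in 'e/A', 'V' or 'mV'."""
        zs = self.axes()[2]
        ramp_v = self.external_ramp_at(zs)  # volts
        vals_v = self.values * COULOMB_V_A_PER_E + ramp_v[None, None, :]
        if unit == "V":
            return vals_v
        if unit == "mV":
            return vals_v * 1e3
        if unit == "e/A":
            return vals_v / COULOMB_V_A_PER_E
        raise ValueError(f"unknown unit {unit!r}")


def external_ramp(z, voltage: float, z0: float, lz: float,
                  depolarizing_positive: bool = True):
    """Linear potential ramp with a total drop of ``voltage`` across the box.

    With ``depolarizing_positive`` the potential is ``voltage`` at the low-z
    face (z = z0) and 0 at the high-z face (z = z0 + lz); the gradient
    magnitude is voltage / lz.
    """
    if lz <= 0:
        raise ValueError("box length must be positive")
    frac = (np.asarray(z, dtype=float) - z0) / lz
    ramp = voltage * (1.0 - frac)
    if not depolarizing_positive:
        ramp = voltage * frac
    return ramp


def _grid_shape(box, spacing):
    """Node counts per axis; the effective box is n * spacing (>= box)."""
    n = np.ceil(np.asarray(box, dtype=float) / spacing - 1e-9).astype(int)
    return np.maximum(n, 1)


def smear_charges(
    frame_coords: np.ndarray, atoms: AtomTable | np.ndarray, spec: SmearingSpec,
    box, origin=(0.0, 0.0, 0.0),
) -> ScalarGrid:
    """Accumulate Gaussian-smeared charges on a periodic grid (e/A^3).

    ``atoms`` may be an AtomTable (partial charges used) or a plain charge
    array.  Atoms are wrapped into the box; the Gaussian tail is truncated
    where it falls below 1e-10 of its peak, and periodic images within the
    truncation radius are included via minimum-image voxel distances.
    """
    charges = (atoms.partial_charge if isinstance(atoms, AtomTable)
               else np.asarray(atoms, dtype=float))
    coords = np.asarray(frame_coords, dtype=float)
    if coords.shape != (len(charges), 3):
        raise ValueError("coordinates and charges disagree in length")
    box = np.asarray(box, dtype=float)
    origin = np.asarray(origin, dtype=float)
    h = spec.grid_spacing
    shape = _grid_shape(box, h)
    eff_box = shape * h
    rho = np.zeros(shape)
    prefac = (spec.beta / np.sqrt(np.pi)) ** 3
    # The 3D Gaussian factorises, and so does the sum over periodic images:
    # sum over image vectors of exp(-b^2 |d + nL|^2) is the product over
    # axes of the per-axis image sums.  This stays exact for boxes smaller
    # than the truncation diameter.
    for q, r in zip(charges, coords):
        if q == 0.0:
            continue
        rel = np.mod(r - origin, eff_box)  # wrap into the box
        per_axis = []
        for d in range(3):
            delta = np.arange(shape[d]) * h - rel[d]
            m_max = int(np.ceil((spec.cutoff + eff_box[d]) / eff_box[d]))
            acc = np.zeros(shape[d])
            for m in range(-m_max, m_max + 1):
                dd = delta + m * eff_box[d]
                acc += np.where(np.abs(dd) <= spec.cutoff,
                                np.exp(-spec.beta ** 2 * dd ** 2), 0.0)
            per_axis.append(acc)
        gx, gy, gz = per_axis
        nzx, nzy, nzz = (np.flatnonzero(g) for g in per_axis)
        if len(nzx) == 0 or len(nzy) == 0 or len(nzz) == 0:
            continue
        rho[np.ix_(nzx, nzy, nzz)] += (q * prefac) * (
            gx[nzx, None, None] * gy[None, nzy, None] * gz[None, None, nzz]
        )
    return ScalarGrid(origin=origin, spacing=h, values=rho, periodic=True,
                      units_label="e/A^3")


def solve_poisson(density: ScalarGrid, *, depolarizing_positive: bool = True,
                  applied_voltage: float = 0.0) -> PotentialGrid:
    """Spectral periodic Poisson solve: laplacian(phi) = -4 pi rho.

    The k = 0 mode is zeroed (mean-zero gauge); a nonzero net charge is
    therefore neutralised by an implicit uniform background and flagged.
    phi is returned in e/A.
    """
    if not density.periodic:
        raise ValueError("solver requires a periodic grid")
    rho = density.values
    h = density.spacing
    net = float(rho.sum() * h ** 3)
    k = [2 * np.pi * np.fft.fftfreq(n, d=h) for n in rho.shape]
    k2 = (k[0][:, None, None] ** 2 + k[1][None, :, None] ** 2
          + k[2][None, None, :] ** 2)
    rho_k = np.fft.fftn(rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_k = 4 * np.pi * rho_k / k2
    phi_k[0, 0, 0] = 0.0
    phi = np.real(np.fft.ifftn(phi_k))
    lz = rho.shape[2] * h
    return PotentialGrid(
        origin=density.origin, spacing=h, values=phi, periodic=True,
        units_label="e/A", applied_voltage=applied_voltage, box_lz=lz,
        neutralized=abs(net) > 1e-6, depolarizing_positive=depolarizing_positive,
    )


def add_external_field(grid: PotentialGrid, voltage: float) -> PotentialGrid:
    """Attach a membrane voltage to the grid as a separate linear ramp.

    The charge-generated values are untouched; the ramp (total drop
    ``voltage`` over L_z, i.e. a gradient of magnitude V / L_z) is applied
    when exporting via :meth:`PotentialGrid.total_values`.
    """
    if grid.box_lz <= 0:
        raise ValueError("grid has no box length along z")
    return PotentialGrid(
        origin=grid.origin, spacing=grid.spacing, values=grid.values.copy(),
        periodic=grid.periodic, units_label=grid.units_label,
        applied_voltage=grid.applied_voltage + voltage, box_lz=grid.box_lz,
        neutralized=grid.neutralized,
        depolarizing_positive=grid.depolarizing_positive,
    )


def average_potential(
    traj: Trajectory, atoms: AtomTable, spec: SmearingSpec,
    frames=None, voltage: float = 0.0, origin=(0.0, 0.0, 0.0),
) -> PotentialGrid:
    """Arithmetic mean of per-frame potential maps on a common grid.

    Frames must share the periodic box to within 1% (constant-volume runs).
    """
    frames = list(range(traj.n_frames)) if frames is None else list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    box0 = traj.box[frames[0]]
    acc = None
    for f in frames:
        if np.any(np.abs(traj.box[f] - box0) / box0 > 0.01):
            raise ValueError(
                f"frame {f} box deviates by more than 1% from frame {frames[0]}"
            )
        rho = smear_charges(traj.coordinates[f], atoms, spec, box0, origin)
        phi = solve_poisson(rho)
        acc = phi.values if acc is None else acc + phi.values
        template = phi
    out = template
    out.values = acc / len(frames)
    return add_external_field(out, voltage) if voltage else out


def potential_at(grid: ScalarGrid, points) -> np.ndarray:
    """Trilinear interpolation of the grid at arbitrary points.

    Points outside the grid raise (no extrapolation).  At voxel centers the
    stored values are returned exactly.
    """
    interp = RegularGridInterpolator(grid.axes(), grid.values,
                                     bounds_error=True, method="linear")
    return interp(np.atleast_2d(np.asarray(points, dtype=float)))


def plane_slice(grid: ScalarGrid, anchors, resolution: float = 1.0,
                extent: float | None = None):
    """Sample the grid on the plane through three anchor points.

    The raster is centered on the first anchor, spanned by in-plane unit
    vectors u (toward the second anchor) and v (orthogonal complement of
    the third).  Returns ``(values 2D, u_coords, v_coords)``.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in anchors)
    u = b - a
    nu = np.linalg.norm(u)
    w = c - a
    if nu < 1e-9:
        raise ValueError("first two anchors coincide")
    u = u / nu
    v = w - np.dot(w, u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise ValueError("anchors are collinear")
    v = v / nv
    if extent is None:
        spans = [grid.spacing * (s - 1) for s in grid.shape]
        extent = min(spans) / 2
    coords = np.arange(-extent, extent + 1e-9, resolution)
    pts = (a[None, None, :] + coords[:, None, None] * u[None, None, :]
           + coords[None, :, None] * v[None, None, :])
    vals = potential_at(grid, pts.reshape(-1, 3)).reshape(len(coords), len(coords))
    return vals, coords, coords
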