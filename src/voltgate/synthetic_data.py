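"""Synthetic input generators with planted ground truth.

Every downstream stage of the package can be exercised without any MD data:
this module fabricates (i) ideal alpha-helix bundles at prescribed tilts,
(ii) multivariate-Gaussian residue fluctuation ensembles with planted
covariance/community structure, (iii) lambda-resolved mean-force curves
with closed-form integrals for thermodynamic integration, (iv) linear-slab
charging systems whose coupling fractions equal planted membrane depths
exactly, and (v) ion z(t) tracks with an exact number of full slab
crossings.

All generators are seed-deterministic and return their ground truth
alongside the data so it can serve directly as a test oracle.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core_io import AtomTable, Trajectory
from .units import KCAL_MOL_PER_EV

__all__ = [
    "HarmonicEnsembleSpec",
    "TIProfileSpec",
    "IonTrackSpec",
    "SlabCouplingSystem",
    "make_helix_bundle",
    "sample_harmonic_ensemble",
    "make_ti_dataset",
    "make_slab_coupling_system",
    "make_ion_tracks",
    "two_block_covariance",
    "two_block_contact_map",
]

# ideal alpha-helix geometry
_HELIX_RISE = 1.5  # A per residue
_HELIX_TWIST = 100.0  # degrees per residue
_HELIX_RADIUS = 2.3  # A, C-alpha distance from axis

# sidechain proxy atoms added for charged residue names
_PROXY_ATOMS = {"ARG": "CZ", "ASP": "CG", "GLU": "CD", "LYS": "NZ"}
_PROXY_CHARGE = {"ARG": 1.0, "ASP": -1.0, "GLU": -1.0, "LYS": 1.0}


@dataclass
class HarmonicEnsembleSpec:
    """I.i.d. multivariate-normal node displacements around fixed means.

    ``covariance`` may be (n, n) — per-node scalar covariance applied
    independently to each Cartesian component — or (3n, 3n) over the full
    displacement vector.  Frames are statistically independent: every
    in-scope network statistic depends only on the stationary distribution.
    """

    n_nodes: int
    mean_positions: np.ndarray
    covariance: np.ndarray
    n_frames: int
    seed: int = 0

    def __post_init__(self):
        self.mean_positions = np.asarray(self.mean_positions, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean_positions.shape != (self.n_nodes, 3):
            raise ValueError("mean_positions must have shape (n_nodes, 3)")
        n, n3 = self.n_nodes, 3 * self.n_nodes
        if self.covariance.shape not in ((n, n), (n3, n3)):
            raise ValueError("covariance must be (n, n) or (3n, 3n)")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() < -1e-8:
            raise ValueError("covariance must be positive semi-definite")


@dataclass
class TIProfileSpec:
    """A mean-force profile over lambda with a closed-form integral.

    ``profile_kind``: ``constant`` | ``linear`` | ``quadratic`` |
    ``tabulated``.  For polynomial kinds, ``coefficients`` are ascending
    polynomial coefficients in lambda (constant uses the first, linear the
    first two, quadratic the first three).  For ``tabulated`` they are the
    per-window values themselves (no closed-form integral).
    """

    profile_kind: str
    coefficients: list
    noise_sd: float = 0.0  # kcal/mol on each window's mean force
    seed: int = 0

    _ORDERS = {"constant": 1, "linear": 2, "quadratic": 3}

    def evaluate(self, lambdas: np.ndarray) -> np.ndarray:
        lambdas = np.asarray(lambdas, dtype=float)
        if self.profile_kind == "tabulated":
            vals = np.asarray(self.coefficients, dtype=float)
            if vals.shape != lambdas.shape:
                raise ValueError("tabulated profile length must match lambda grid")
            return vals
        order = self._ORDERS.get(self.profile_kind)
        if order is None:
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}")
        coeffs = np.zeros(order)
        coeffs[: len(self.coefficients[:order])] = self.coefficients[:order]
        return np.polynomial.polynomial.polyval(lambdas, coeffs)

    def exact_integral(self) -> float:
        """Closed-form integral of the profile over lambda in [0, 1]."""
        if self.profile_kind == "tabulated":
            raise ValueError("tabulated profiles have no closed-form integral")
        order = self._ORDERS[self.profile_kind]
        coeffs = np.zeros(order)
        coeffs[: len(self.coefficients[:order])] = self.coefficients[:order]
        return float(sum(c / (k + 1) for k, c in enumerate(coeffs)))


@dataclass
class IonTrackSpec:
    """Planted permeation tracks: exact up/down full crossings plus feints."""

    n_events_up: int
    n_events_down: int
    duration: float  # ns
    jitter_sd: float = 0.3  # A
    seed: int = 0
    n_distractors: int = 1  # tracks that enter the slab but never cross


def make_helix_bundle(
    n_helices: int,
    tilt_deg,
    n_residues: int = 27,
    seed: int = 0,
    first_residue: int = 109,
    bundle_radius: float = 12.0,
    residue_names=None,
    chain_id: str = "A",
):
    """Build ideal alpha-helices (1.5 A rise, 100 deg twist per residue).

    Each helix is generated along +z, rotated about x by its requested tilt
    and placed on a circle of ``bundle_radius``.  Atoms per residue: CA on
    the helical curve and a CB placeholder displaced radially outward;
    charged residue names additionally get their sidechain proxy atom
    (CZ for Arg, carboxyl carbon for Asp/Glu).  Residue numbering is
    contiguous across helices starting at ``first_residue``.

    Returns ``(AtomTable, coords)`` with the principal axis of each helix
    within 0.5 degrees of the requested tilt.
    """
    tilts = np.atleast_1d(np.asarray(tilt_deg, dtype=float))
    if len(tilts) == 1:
        tilts = np.repeat(tilts, n_helices)
    if len(tilts) != n_helices:
        raise ValueError("need one tilt per helix")
    if np.any((tilts < 0) | (tilts >= 90)):
        raise ValueError("tilt must be in [0, 90)")
    if residue_names is None:
        residue_names = ["ALA"] * n_residues

    rows = {k: [] for k in (
        "atom_id", "atom_name", "residue_id", "residue_name",
        "chain_id", "element", "partial_charge", "vdw_radius")}
    coords = []
    atom_id = 1
    resid = first_residue
    for h in range(n_helices):
        phase = np.deg2rad(_HELIX_TWIST) * np.arange(n_residues)
        z = _HELIX_RISE * np.arange(n_residues)
        z -= z.mean()
        ca = np.column_stack(
            [_HELIX_RADIUS * np.cos(phase), _HELIX_RADIUS * np.sin(phase), z]
        )
        cb = np.column_stack(
            [(_HELIX_RADIUS + 1.5) * np.cos(phase),
             (_HELIX_RADIUS + 1.5) * np.sin(phase), z]
        )
        cz = np.column_stack(
            [(_HELIX_RADIUS + 4.0) * np.cos(phase),
             (_HELIX_RADIUS + 4.0) * np.sin(phase), z]
        )
        theta = np.deg2rad(tilts[h])
        rot = np.array(
            [[1, 0, 0],
             [0, np.cos(theta), -np.sin(theta)],
             [0, np.sin(theta), np.cos(theta)]]
        )
        ang = 2 * np.pi * h / max(n_helices, 1)
        offset = np.array(
            [bundle_radius * np.cos(ang) * (n_helices > 1),
             bundle_radius * np.sin(ang) * (n_helices > 1), 0.0]
        )
        ca, cb, cz = (a @ rot.T + offset for a in (ca, cb, cz))
        for r in range(n_residues):
            rname = residue_names[r % len(residue_names)] if n_helices == 1 else (
                residue_names[r] if r < len(residue_names) else "ALA")
            names = ["CA", "CB"]
            pts = [ca[r], cb[r]]
            if rname in _PROXY_ATOMS:
                names.append(_PROXY_ATOMS[rname])
                pts.append(cz[r])
            for nm, pt in zip(names, pts):
                rows["atom_id"].append(atom_id)
                rows["atom_name"].append(nm)
                rows["residue_id"].append(resid)
                rows["residue_name"].append(rname)
                rows["chain_id"].append(chain_id)
                rows["element"].append("C" if nm.startswith("C") else "N")
                rows["partial_charge"].append(
                    _PROXY_CHARGE.get(rname, 0.0) if nm == _PROXY_ATOMS.get(rname) else 0.0
                )
                rows["vdw_radius"].append(1.7)
                coords.append(pt)
                atom_id += 1
            resid += 1
    return AtomTable(**rows), np.asarray(coords)


def sample_harmonic_ensemble(spec: HarmonicEnsembleSpec) -> Trajectory:
    """Draw i.i.d. frames from the planted multivariate normal.

    Identical seeds give bitwise-identical trajectories.  The box is a cube
    comfortably larger than the node cloud (the ensemble has no periodicity).
    """
    rng = np.random.default_rng(spec.seed)
    n, f = spec.n_nodes, spec.n_frames
    # Cholesky with a tiny jitter fallback for PSD-but-singular inputs
    cov = spec.covariance
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    if cov.shape[0] == n:
        # same node-level covariance independently per Cartesian component
        z = rng.standard_normal((f, 3, n))
        disp = np.einsum("ij,fcj->fci", chol, z).transpose(0, 2, 1)
    else:
        z = rng.standard_normal((f, 3 * n))
        disp = (z @ chol.T).reshape(f, n, 3)
    coords = spec.mean_positions[None, :, :] + disp
    extent = np.abs(spec.mean_positions).max() + 6 * np.sqrt(max(cov.max(), 1e-12)) + 10
    box = np.full(3, 2 * extent)
    return Trajectory(coordinates=coords, box=np.tile(box, (f, 1)), timestep=0.001)


def two_block_covariance(n_nodes: int, block_r: float = 0.8, cross_r: float = 0.0,
                         variance: float = 1.0) -> np.ndarray:
    """Two equal blocks with planted intra-/inter-block displacement correlation."""
    half = n_nodes // 2
    cov = np.full((n_nodes, n_nodes), cross_r * variance)
    cov[:half, :half] = block_r * variance
    cov[half:, half:] = block_r * variance
    np.fill_diagonal(cov, variance)
    if np.linalg.eigvalsh(cov).min() < -1e-10:
        raise ValueError("requested correlations are not jointly PSD")
    return cov


def two_block_contact_map(n_nodes: int, node_ids=None):
    """Contact topology matching :func:`two_block_covariance`: each block is
    fully connected internally and a single bridge edge joins the last node
    of the first block to the first node of the second.

    This is the planted-partition topology for community-recovery tests:
    the bridge is the only inter-block contact, as for two packed helices
    touching at one interface.
    """
    from .dynamic_network import ContactMap

    half = n_nodes // 2
    vals = np.zeros((n_nodes, n_nodes), dtype=bool)
    vals[:half, :half] = True
    vals[half:, half:] = True
    np.fill_diagonal(vals, False)
    vals[half - 1, half] = vals[half, half - 1] = True
    if node_ids is None:
        node_ids = list(range(1, n_nodes + 1))
    return ContactMap(values=vals, node_ids=list(node_ids),
                      neighbor_exclusion=0)


def make_ti_dataset(spec: TIProfileSpec, lambdas=None, *, residue_id: int = 0,
                    state: str = "closed", voltage: float = 0.0, q: float = 1.0,
                    n_blocks: int = 0):
    """Evaluate a mean-force profile on a lambda grid as a TIDataset.

    With ``spec.noise_sd > 0`` the per-window mean force is perturbed by
    Gaussian noise of that standard deviation; if ``n_blocks`` > 0, a block
    series is synthesised whose block mean equals the noisy mean force and
    whose block-averaged standard error is (in expectation) ``noise_sd``.
    The closed-form integral is attached as ``ground_truth_dg`` (kcal/mol).
    """
    from .gating_charge import TIDataset

    if lambdas is None:
        lambdas = np.linspace(0.0, 1.0, 11)
    lambdas = np.asarray(lambdas, dtype=float)
    truth = spec.evaluate(lambdas)
    rng = np.random.default_rng(spec.seed)
    blocks = None
    if spec.noise_sd > 0 and n_blocks > 1:
        blocks = truth[:, None] + spec.noise_sd * np.sqrt(n_blocks) * \
            rng.standard_normal((len(lambdas), n_blocks))
        forces = blocks.mean(axis=1)
    elif spec.noise_sd > 0:
        forces = truth + spec.noise_sd * rng.standard_normal(len(lambdas))
    else:
        forces = truth.copy()
    gt = None
    if spec.profile_kind != "tabulated":
        gt = spec.exact_integral()
    return TIDataset(
        residue_id=residue_id, state=state, voltage=voltage, q=q,
        lambdas=lambdas, mean_forces=forces, block_series=blocks,
        ground_truth_dg=gt,
    )


@dataclass
class SlabCouplingSystem:
    """Linear-field slab realisation of the charging-free-energy bookkeeping.

    A residue at fractional membrane depth d with charge q experiences
    ``dG(V, q) = q * V * d`` (eV), so its coupling fraction equals d exactly
    and the planted gating charge is ``sum_i q_i (d_closed,i - d_open,i)``.
    """

    residue_ids: list
    charges: np.ndarray
    depths_closed: np.ndarray
    depths_open: np.ndarray
    v1: float
    v2: float
    datasets: list  # TIDataset per (residue, state, voltage)
    planted_f_closed: np.ndarray = field(init=False)
    planted_f_open: np.ndarray = field(init=False)
    planted_dq: np.ndarray = field(init=False)
    planted_dQ: float = field(init=False)

    def __post_init__(self):
        self.planted_f_closed = self.depths_closed.copy()
        self.planted_f_open = self.depths_open.copy()
        self.planted_dq = self.charges * (self.depths_closed - self.depths_open)
        self.planted_dQ = float(self.planted_dq.sum())


def make_slab_coupling_system(
    depths_closed, depths_open=None, charges=None, v1: float = 0.0,
    v2: float = 0.75, residue_ids=None, noise_sd: float = 0.0,
    n_blocks: int = 64, seed: int = 0, lambdas=None,
) -> SlabCouplingSystem:
    """Build TI datasets for a linear-slab system with known coupling fractions.

    In a uniform field the charging free energy is linear in lambda:
    ``H(lambda) = lambda * q * V * d`` so each window's mean force is the
    constant ``q * V * d`` (converted to kcal/mol).  ``noise_sd`` (kcal/mol)
    perturbs the window mean forces; with the default 0 the recovery is
    exact to floating-point roundoff.
    """
    depths_closed = np.atleast_1d(np.asarray(depths_closed, dtype=float))
    n = len(depths_closed)
    depths_open = (np.atleast_1d(np.asarray(depths_open, dtype=float))
                   if depths_open is not None else depths_closed.copy())
    charges = (np.atleast_1d(np.asarray(charges, dtype=float))
               if charges is not None else np.ones(n))
    if residue_ids is None:
        residue_ids = list(range(1, n + 1))
    if not (len(depths_open) == len(charges) == len(residue_ids) == n):
        raise ValueError("per-residue inputs must have equal length")
    for d in (depths_closed, depths_open):
        if np.any((d < 0) | (d > 1)):
            raise ValueError("depths must lie in [0, 1]")
    datasets = []
    for k, rid in enumerate(residue_ids):
        for state, depth in (("closed", depths_closed[k]), ("open", depths_open[k])):
            for v in (v1, v2):
                force_kcal = charges[k] * v * depth * KCAL_MOL_PER_EV
                tag = zlib.crc32(f"{rid}|{state}|{v:.9g}".encode()) % 100003
                spec = TIProfileSpec(
                    "constant", [force_kcal], noise_sd=noise_sd,
                    seed=(seed * 7919 + tag) % (2**31 - 1),
                )
                datasets.append(
                    make_ti_dataset(spec, lambdas, residue_id=rid, state=state,
                                    voltage=v, q=charges[k], n_blocks=n_blocks)
                )
    return SlabCouplingSystem(
        residue_ids=list(residue_ids), charges=charges,
        depths_closed=depths_closed, depths_open=depths_open,
        v1=v1, v2=v2, datasets=datasets,
    )


def make_ion_tracks(spec: IonTrackSpec, slab=(-5.0, 5.0), n_steps_per_event: int = 200):
    """Generate ion z(t) tracks whose full-slab crossing counts are planted.

    One track per genuine event: the ion approaches from its entry side,
    lingers with bounded jitter, crosses the slab monotonically (plus
    bounded jitter that cannot re-cross a boundary) and leaves through the
    far side.  ``n_distractors`` additional tracks enter through one
    boundary, wander inside the slab and retreat through the same boundary:
    they must never be counted.

    Returns ``(tracks, ground_truth)`` where ``tracks`` is a list of
    ``(ion_id, times_ns, z_values)`` and ``ground_truth`` a dict with the
    planted up/down counts.
    """
    z_lo, z_hi = slab
    width = z_hi - z_lo
    rng = np.random.default_rng(spec.seed)
    margin = width / 4.0
    jitter_amp = min(spec.jitter_sd, 0.8 * margin)

    def one_crossing(up: bool):
        n = n_steps_per_event
        # approach: safely outside the entry boundary
        start = (z_lo - 2 * width) if up else (z_hi + 2 * width)
        end = (z_hi + 2 * width) if up else (z_lo - 2 * width)
        base = np.linspace(start, end, n)
        jit = np.clip(jitter_amp * rng.standard_normal(n), -margin, margin)
        z = base + jit
        # enforce a single monotone boundary crossing: clamp so that once a
        # boundary is passed the track never returns behind it
        if up:
            z = np.maximum.accumulate(np.minimum(z, end))
        else:
            z = np.minimum.accumulate(np.maximum(z, end))
        return z

    def one_feint():
        n = n_steps_per_event
        t = np.linspace(0, np.pi, n)
        # enters through the lower boundary, turns around inside, exits back
        depth = z_lo + 0.6 * width * np.sin(t)
        jit = np.clip(jitter_amp * rng.standard_normal(n), -margin, margin)
        z = depth + 0.2 * jit
        return np.minimum(z, z_hi - 0.1 * width)  # never reaches the top

    tracks = []
    ion = 0
    total = spec.n_events_up + spec.n_events_down + spec.n_distractors
    seg = spec.duration / max(total, 1)
    t0 = 0.0
    for _ in range(spec.n_events_up):
        z = one_crossing(up=True)
        tracks.append((ion, t0 + np.linspace(0, seg, len(z)), z)); ion += 1; t0 += seg
    for _ in range(spec.n_events_down):
        z = one_crossing(up=False)
        tracks.append((ion, t0 + np.linspace(0, seg, len(z)), z)); ion += 1; t0 += seg
    for _ in range(spec.n_distractors):
        z = one_feint()
        tracks.append((ion, t0 + np.linspace(0, seg, len(z)), z)); ion += 1; t0 += seg
    truth = {"n_up": spec.n_events_up, "n_down": spec.n_events_down,
             "slab": (z_lo, z_hi), "duration_ns": spec.duration}
    return tracks, truth
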