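"""Mutual-information residue networks and Laplacian information flow.

Each node's fluctuation is summarised as x_t = |r_t - <r>|, the distance
from its trajectory-mean (equilibrium) position per frame.  Differential
entropies H_i are estimated by fitting a Gaussian mixture model (GMM) to
the samples and evaluating H = -(1/N) sum_n ln rho(x_n); the mixture size
is chosen by BIC over 1..max_components with a fixed seed and multiple
restarts.  Pairwise mutual information is M_ij = H_i + H_j - H_ij with the
joint entropy from a 2D GMM on paired samples; small negative estimates (a
finite-sample artifact) are clamped to zero and flagged.

The flow network masks M by the boolean contact map, A_ij = contact * M_ij,
and treats A as electrical conductances: with the graph Laplacian
L = D - A (D_ii = sum_j A_ij), injecting one unit of current at a source
node and extracting it at sink nodes gives node potentials P from the
reduced system L~ P = b (sink rows/columns removed, sink potentials 0) and
the per-node information flow

    f_i = 1/2 sum_j |P_i - P_j| A_ij,

i.e. half the total current through node i; a sole source or sink carries
f = 0.5 exactly.  Entropies and MI are reported in nats.

A signed-sample "test mode" exists in the estimators (they accept any
real-valued samples), so closed-form Gaussian oracles apply directly;
production callers pass the non-negative distance series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.mixture import GaussianMixture

from .core_io import AtomTable, Trajectory, select_atoms
from .dynamic_network import ContactMap

__all__ = [
    "EntropyEstimate",
    "MIResult",
    "FlowResult",
    "fluctuation_series",
    "gmm_entropy",
    "mutual_information",
    "mi_matrix",
    "flow_network",
    "information_flow",
]

#: reported MI (nats) when two series are numerically identical, where the
#: continuous MI diverges; flagged as degenerate in the result
MI_SATURATION = 20.0


@dataclass
class EntropyEstimate:
    h: float  # nats
    n_components: int
    bic: float
    n_samples: int


@dataclass
class MIResult:
    value: float  # nats
    h_i: float
    h_j: float
    h_ij: float
    clamped: bool = False
    degenerate: bool = False


@dataclass
class FlowResult:
    adjacency: np.ndarray  # A = contact-masked MI
    node_ids: list
    laplacian: np.ndarray = field(init=False)
    degree: np.ndarray = field(init=False)
    potentials: np.ndarray | None = None
    flow: np.ndarray | None = None
    source: int | None = None
    sinks: list | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
            raise ValueError("adjacency must be square symmetric")
        np.fill_diagonal(a, 0.0)
        self.adjacency = a
        self.degree = np.diag(a.sum(axis=1))
        self.laplacian = self.degree - a


def fluctuation_series(traj: Trajectory, atom_index: int) -> np.ndarray:
    """x_t = |r_t - <r>|: distance of one atom from its mean position."""
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    pos = traj.coordinates[:, atom_index, :]
    return np.linalg.norm(pos - pos.mean(axis=0), axis=1)


def node_fluctuations(traj: Trajectory, atoms: AtomTable,
                      node_selection="name CA") -> tuple[np.ndarray, list]:
    """Fluctuation series for every node; returns (series (n_frames, n), ids)."""
    idx = select_atoms(atoms, node_selection)
    pos = traj.coordinates[:, idx, :]
    x = np.linalg.norm(pos - pos.mean(axis=0), axis=2)
    return x, atoms.residue_id[idx].tolist()


def gmm_entropy(samples, max_components: int = 5, seed: int = 0,
                n_init: int = 3) -> EntropyEstimate:
    """Differential entropy (nats) via a BIC-selected Gaussian mixture.

    ``samples`` is (n,) or (n, d).  Requires >= 50 samples; all-equal
    samples raise (the differential entropy diverges to -inf).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 50:
        raise ValueError("need at least 50 samples for a stable GMM fit")
    if np.all(np.ptp(x, axis=0) < 1e-12):
        raise ValueError("degenerate (constant) samples: entropy is -inf")
    best = None
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=n_init,
                             reg_covar=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(x)
        bic = gm.bic(x)
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    bic, k, gm = best
    h = float(-np.mean(gm.score_samples(x)))
    return EntropyEstimate(h=h, n_components=k, bic=float(bic), n_samples=n)


def mutual_information(series_i, series_j, max_components: int = 5,
                       seed: int = 0, n_init: int = 3) -> MIResult:
    """M_ij = H_i + H_j - H_ij with the joint entropy from a 2D GMM.

    Numerically identical (or perfectly dependent) series saturate at
    ``MI_SATURATION`` nats with a degeneracy flag; small negative estimates
    are clamped to 0 and flagged.
    """
    xi = np.asarray(series_i, dtype=float).ravel()
    xj = np.asarray(series_j, dtype=float).ravel()
    if xi.shape != xj.shape:
        raise ValueError(f"length mismatch: {xi.shape[0]} vs {xj.shape[0]}")
    hi = gmm_entropy(xi, max_components, seed, n_init)
    hj = gmm_entropy(xj, max_components, seed, n_init)
    corr = np.corrcoef(xi, xj)[0, 1]
    if abs(corr) > 1 - 1e-9:
        return MIResult(value=MI_SATURATION, h_i=hi.h, h_j=hj.h,
                        h_ij=np.nan, degenerate=True)
    hij = gmm_entropy(np.column_stack([xi, xj]), max_components, seed, n_init)
    m = hi.h + hj.h - hij.h
    clamped = m < 0
    return MIResult(value=max(m, 0.0), h_i=hi.h, h_j=hj.h, h_ij=hij.h,
                    clamped=clamped)


def mi_matrix(series: np.ndarray, contacts: ContactMap | None = None,
              max_components: int = 5, seed: int = 0,
              n_init: int = 3) -> np.ndarray:
    """Pairwise MI (nats) over node fluctuation series (n_frames, n_nodes).

    With a contact map, only contacting pairs are estimated (the rest are
    masked away downstream regardless); diagonal is 0.
    """
    n = series.shape[1]
    m = np.zeros((n, n))
    n_clamped = 0
    for i in range(n):
        for j in range(i + 1, n):
            if contacts is not None and not contacts.values[i, j]:
                continue
            res = mutual_information(series[:, i], series[:, j],
                                     max_components, seed, n_init)
            m[i, j] = m[j, i] = res.value
            n_clamped += res.clamped
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} negative MI estimate(s) to 0")
    return m


def flow_network(contacts: ContactMap, m: np.ndarray) -> FlowResult:
    """A = contact-mask applied elementwise to the MI matrix; L = D - A."""
    m = np.asarray(m, dtype=float)
    n = len(contacts.node_ids)
    if m.shape != (n, n):
        raise ValueError("MI matrix shape must match contact map")
    a = np.where(contacts.values, m, 0.0)
    return FlowResult(adjacency=a, node_ids=list(contacts.node_ids))


def information_flow(flowres: FlowResult, source, sinks) -> FlowResult:
    """Solve the reduced Laplacian system and compute per-node flow.

    One unit of current enters at ``source`` and exits at ``sinks``
    (potential 0 at every sink).  Returns a new FlowResult carrying the
    full potential vector P and f_i = 1/2 sum_j |P_i - P_j| A_ij.
    """
    ids = flowres.node_ids
    if np.isscalar(sinks):
        sinks = [sinks]
    if source in sinks:
        raise ValueError("source must not be a sink")
    try:
        src = ids.index(source)
        snk = [ids.index(s) for s in sinks]
    except ValueError as err:
        raise ValueError(f"unknown node: {err}") from None
    a = flowres.adjacency
    g = nx.from_numpy_array(a)
    comp = nx.node_connected_component(g, src)
    if any(s not in comp for s in snk):
        raise ValueError("source and sink(s) are not in one connected component")
    n = a.shape[0]
    keep = np.array([i for i in range(n) if i not in snk])
    lred = flowres.laplacian[np.ix_(keep, keep)]
    b = np.zeros(len(keep))
    b[np.flatnonzero(keep == src)[0]] = 1.0
    try:
        p_red = np.linalg.solve(lred, b)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular reduced Laplacian: {err}") from None
    p = np.zeros(n)
    p[keep] = p_red
    f = 0.5 * np.sum(np.abs(p[:, None] - p[None, :]) * a, axis=1)
    out = FlowResult(adjacency=a.copy(), node_ids=list(ids))
    out.potentials = p
    out.flow = f
    out.source = source
    out.sinks = list(sinks)
    return out
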