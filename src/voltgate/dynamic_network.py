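"""Dynamic residue interaction networks from trajectory fluctuations.

Residues are nodes at their C-alpha positions.  An edge exists between two
residues whose minimum heavy-atom distance is within a cutoff (default
5 A) for at least an occupancy fraction of frames (default 75%), and is
weighted by w_ij = -ln |C_ij| where C_ij is the normalised covariance of
the 3D displacement fluctuations.  Strong coupling (|C| near 1) gives
short edges, so minimum-total-weight paths are the strongest allosteric
coupling routes: the optimal path comes from Floyd-Warshall with a
deterministic (lexicographic) tie-break, suboptimal paths are all simple
paths within a fractional length tolerance of the optimum (default:
strictly less than 1.5x), and communities are obtained by Girvan-Newman
divisive clustering at maximum modularity.

The absolute value in -ln |C_ij| extends the weighting to anti-correlated
pairs (the convention of the dynamic-network tooling in this field); the
log base only rescales path lengths and never changes their ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core_io import AtomTable, Trajectory, select_atoms

__all__ = [
    "CorrelationMatrix",
    "ContactMap",
    "PathSet",
    "CommunityPartition",
    "correlation_matrix",
    "contact_map",
    "build_network",
    "optimal_path",
    "suboptimal_paths",
    "communities",
]


@dataclass
class CorrelationMatrix:
    """Normalised displacement covariance C_ij in [-1, 1] over nodes."""

    values: np.ndarray
    node_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match node count")


@dataclass
class ContactMap:
    """Boolean residue adjacency from heavy-atom distances."""

    values: np.ndarray  # bool (n, n)
    node_ids: list
    cutoff: float = 5.0
    occupancy: float = 0.75
    neighbor_exclusion: int = 1


@dataclass
class PathSet:
    source: int
    sink: int
    optimal: list
    optimal_length: float
    suboptimal: list = field(default_factory=list)  # [(length, path), ...]
    tolerance: float = 0.5
    truncated: bool = False


@dataclass
class CommunityPartition:
    membership: dict  # node -> community id
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def correlation_matrix(traj: Trajectory, atoms: AtomTable,
                       node_selection="name CA") -> CorrelationMatrix:
    """C_ij = <dri . drj> / sqrt(<dri^2><drj^2>) over 3D displacement
    fluctuations about the trajectory-mean node positions."""
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    idx = select_atoms(atoms, node_selection)
    node_ids = atoms.residue_id[idx].tolist()
    pos = traj.coordinates[:, idx, :]
    disp = pos - pos.mean(axis=0)
    cov = np.einsum("fic,fjc->ij", disp, disp) / traj.n_frames
    var = np.diag(cov)
    zero = np.flatnonzero(var <= 1e-14)
    if len(zero):
        bad = [node_ids[i] for i in zero]
        raise ValueError(f"zero-variance node(s): residues {bad}")
    c = cov / np.sqrt(np.outer(var, var))
    return CorrelationMatrix(values=c, node_ids=node_ids)


def contact_map(traj: Trajectory, atoms: AtomTable, node_residues=None,
                cutoff: float = 5.0, occupancy: float = 0.75,
                neighbor_exclusion: int = 1) -> ContactMap:
    """Edge iff the minimum heavy-atom distance between two residues is
    <= cutoff in at least ``occupancy`` of the frames; residue pairs within
    ``neighbor_exclusion`` in sequence are removed (default: covalently
    adjacent residues)."""
    heavy = atoms.heavy_mask()
    if node_residues is None:
        node_residues = sorted(set(atoms.residue_id.tolist()))
    groups = [np.flatnonzero(heavy & (atoms.residue_id == rid))
              for rid in node_residues]
    if any(len(g) == 0 for g in groups):
        empty = [r for r, g in zip(node_residues, groups) if len(g) == 0]
        raise ValueError(f"no heavy atoms for residue(s) {empty}")
    n = len(node_residues)
    sizes = [len(g) for g in groups]
    order = np.concatenate(groups)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    hits = np.zeros((n, n), dtype=int)
    for f in range(traj.n_frames):
        pts = traj.coordinates[f, order]
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        # min over residue blocks on both axes
        dmin = np.minimum.reduceat(
            np.minimum.reduceat(d, starts[:-1], axis=0), starts[:-1], axis=1
        )
        hits += dmin <= cutoff
    frac = hits / traj.n_frames
    contacts = frac >= occupancy
    np.fill_diagonal(contacts, False)
    if neighbor_exclusion > 0:
        rid = np.asarray(node_residues)
        close = np.abs(rid[:, None] - rid[None, :]) <= neighbor_exclusion
        contacts &= ~close
    return ContactMap(values=contacts, node_ids=list(node_residues),
                      cutoff=cutoff, occupancy=occupancy,
                      neighbor_exclusion=neighbor_exclusion)


def build_network(contacts: ContactMap, corr: CorrelationMatrix) -> nx.Graph:
    """Weight contact edges by w = -ln |C_ij|.

    Nodes are residue ids; edge attributes: ``weight`` (the -ln |C| length),
    ``corr`` (C_ij) and ``strength`` (|C_ij|, used for modularity).
    C_ij = 0 edges are dropped with a warning (infinite length).
    """
    if contacts.node_ids != corr.node_ids:
        raise ValueError("contact map and correlation matrix node sets differ")
    c = corr.values
    if np.any(np.abs(c) > 1 + 1e-8):
        raise ValueError("|C_ij| > 1 beyond tolerance")
    g = nx.Graph()
    g.add_nodes_from(contacts.node_ids)
    n = len(contacts.node_ids)
    dropped = 0
    for i in range(n):
        for j in range(i + 1, n):
            if not contacts.values[i, j]:
                continue
            cij = abs(c[i, j])
            if cij == 0.0:
                dropped += 1
                continue
            w = -np.log(min(cij, 1.0))
            g.add_edge(contacts.node_ids[i], contacts.node_ids[j],
                       weight=float(w), corr=float(c[i, j]),
                       strength=float(cij))
    if dropped:
        warnings.warn(f"dropped {dropped} zero-correlation contact edge(s)")
    return g


# ---------------------------------------------------------------------------
# paths
# ---------------------------------------------------------------------------

def _floyd_warshall(g: nx.Graph):
    """All-pairs shortest path lengths (dict of dicts) over 'weight'."""
    nodes = sorted(g.nodes)
    dist = {u: {v: np.inf for v in nodes} for u in nodes}
    for u in nodes:
        dist[u][u] = 0.0
    for u, v, data in g.edges(data=True):
        w = data["weight"]
        if w < dist[u][v]:
            dist[u][v] = dist[v][u] = w
    for k in nodes:
        dk = dist[k]
        for i in nodes:
            dik = dist[i][k]
            if not np.isfinite(dik):
                continue
            di = dist[i]
            for j in nodes:
                alt = dik + dk[j]
                if alt < di[j]:
                    di[j] = alt
    return dist


def _lexicographic_shortest(g: nx.Graph, dist, source, sink, tol=1e-12):
    """Reconstruct the lexicographically smallest shortest path greedily."""
    path = [source]
    node = source
    while node != sink:
        best = None
        for nb in sorted(g.neighbors(node)):
            if nb in path:
                continue
            w = g[node][nb]["weight"]
            if abs(w + dist[nb][sink] - dist[node][sink]) <= tol * max(1, abs(dist[node][sink])):
                best = nb
                break
        if best is None:  # numerical corner: fall back to networkx
            return nx.dijkstra_path(g, source, sink, weight="weight")
        path.append(best)
        node = best
    return path


def optimal_path(g: nx.Graph, source, sink) -> PathSet:
    """Minimum-total-weight (strongest-coupling) path via Floyd-Warshall.

    Ties are broken toward the lexicographically smallest node sequence.
    """
    if source == sink:
        raise ValueError("source and sink must differ")
    for node in (source, sink):
        if node not in g:
            raise ValueError(f"node {node} not in network")
    dist = _floyd_warshall(g)
    if not np.isfinite(dist[source][sink]):
        raise ValueError(f"sink {sink} unreachable from source {source}")
    path = _lexicographic_shortest(g, dist, source, sink)
    return PathSet(source=source, sink=sink, optimal=path,
                   optimal_length=float(dist[source][sink]))


def suboptimal_paths(g: nx.Graph, source, sink, tolerance: float = 0.5,
                     cap: int = 1000) -> PathSet:
    """All simple paths with length strictly below (1 + tolerance) times the
    optimal length, sorted by (length, node sequence), up to ``cap``.

    Enumeration is a depth-first search pruned with Floyd-Warshall
    remaining-distance bounds.  Exceeding ``cap`` sets ``truncated``.
    """
    if source == sink:
        raise ValueError("source and sink must differ")
    dist = _floyd_warshall(g)
    if not np.isfinite(dist[source][sink]):
        raise ValueError(f"sink {sink} unreachable from source {source}")
    base = PathSet(source=source, sink=sink,
                   optimal=_lexicographic_shortest(g, dist, source, sink),
                   optimal_length=float(dist[source][sink]))
    bound = (1.0 + tolerance) * base.optimal_length
    found = []
    truncated = False
    eps = 1e-12 * max(1.0, bound)

    def dfs(node, length, path, visited):
        nonlocal truncated
        if truncated:
            return
        if node == sink:
            found.append((length, list(path)))
            if len(found) > cap:
                truncated = True
            return
        for nb in sorted(g.neighbors(node)):
            if nb in visited:
                continue
            nl = length + g[node][nb]["weight"]
            if nl + dist[nb][sink] >= bound - eps:
                continue
            visited.add(nb)
            path.append(nb)
            dfs(nb, nl, path, visited)
            path.pop()
            visited.remove(nb)

    dfs(source, 0.0, [source], {source})
    found.sort(key=lambda lp: (lp[0], lp[1]))
    if truncated:
        found = found[:cap]
    return PathSet(source=source, sink=sink, optimal=base.optimal,
                   optimal_length=base.optimal_length, suboptimal=found,
                   tolerance=tolerance, truncated=truncated)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _most_valuable_edge(g: nx.Graph):
    """Highest weighted edge-betweenness; ties to the smallest edge label."""
    bet = nx.edge_betweenness_centrality(g, weight="weight")
    top = max(bet.values())
    # deterministic: among ties pick the lexicographically smallest edge
    candidates = [tuple(sorted(e)) for e, b in bet.items() if abs(b - top) < 1e-12]
    return min(candidates)


def communities(g: nx.Graph) -> CommunityPartition:
    """Girvan-Newman divisive clustering; the partition (including the
    undivided one) with maximum modularity on edge strengths is returned."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    base = [frozenset(c) for c in nx.connected_components(g)]
    best_part = base
    best_q = nx.community.modularity(g, base, weight="strength") \
        if g.number_of_edges() else 0.0
    if g.number_of_edges():
        gn = nx.community.girvan_newman(g, most_valuable_edge=_most_valuable_edge)
        for part in gn:
            part = [frozenset(c) for c in part]
            q = nx.community.modularity(g, part, weight="strength")
            if q > best_q + 1e-12:
                best_q, best_part = q, part
    membership = {}
    for cid, comm in enumerate(sorted(best_part, key=lambda c: sorted(c)[0])):
        for node in comm:
            membership[node] = cid
    return CommunityPartition(membership=membership, modularity=float(best_q))
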