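"""Correlation networks, shortest/suboptimal coupling paths, communities."""

import itertools

import networkx as nx
import numpy as np
import pytest

from voltgate.core_io import Trajectory
from voltgate.dynamic_network import (
    ContactMap,
    CorrelationMatrix,
    build_network,
    communities,
    contact_map,
    correlation_matrix,
    optimal_path,
    suboptimal_paths,
)
from voltgate.synthetic_data import (
    HarmonicEnsembleSpec,
    sample_harmonic_ensemble,
    two_block_contact_map,
    two_block_covariance,
)

BOX = np.array([500.0, 500.0, 500.0])


def brute_force_paths(g, source, sink):
    """Exhaustive simple-path enumeration with lengths (test oracle)."""
    out = []
    for path in nx.all_simple_paths(g, source, sink):
        length = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
        out.append((length, path))
    return sorted(out, key=lambda lp: (lp[0], lp[1]))


def random_weighted_graph(rng, n, p=0.35):
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
    return g


class TestCorrelation:
    def test_self_correlation_unity(self, ca_table_factory, rng):
        traj = Trajectory(coordinates=rng.normal(0, 1, (50, 3, 3)) + 100,
                          box=BOX)
        c = correlation_matrix(traj, ca_table_factory(3))
        np.testing.assert_allclose(np.diag(c.values), 1.0, atol=1e-12)

    def test_planted_correlation(self, ca_table_factory):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        traj = sample_harmonic_ensemble(
            HarmonicEnsembleSpec(2, np.zeros((2, 3)), cov, 100_000, seed=1))
        c = correlation_matrix(traj, ca_table_factory(2))
        assert c.values[0, 1] == pytest.approx(0.9, abs=0.02)

    def test_antiphase_motion(self, ca_table_factory):
        t = np.linspace(0, 8 * np.pi, 200)
        coords = np.zeros((200, 2, 3))
        coords[:, 0, 0] = np.sin(t)
        coords[:, 1, 0] = -np.sin(t)
        traj = Trajectory(coordinates=coords + 100, box=BOX)
        c = correlation_matrix(traj, ca_table_factory(2))
        assert c.values[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_zero_variance_named(self, ca_table_factory):
        coords = np.zeros((10, 2, 3)) + 50
        coords[:, 0, 0] += np.linspace(0, 1, 10)
        traj = Trajectory(coordinates=coords, box=BOX)
        with pytest.raises(ValueError, match="2"):
            correlation_matrix(traj, ca_table_factory(2))


class TestContactMap:
    def _traj(self, dists, n_frames):
        """Two single-atom residues separated by dists[f] at frame f."""
        coords = np.zeros((n_frames, 2, 3)) + 50
        coords[:, 1, 0] += np.asarray(dists)
        return Trajectory(coordinates=coords, box=BOX)

    def test_fixed_contact(self, ca_table_factory):
        traj = self._traj([4.2] * 10, 10)
        cm = contact_map(traj, ca_table_factory(2), neighbor_exclusion=0)
        assert cm.values[0, 1]

    def test_occupancy_threshold(self, ca_table_factory):
        dists = [4.0] * 7 + [8.0] * 3  # 70% < 75%
        cm = contact_map(self._traj(dists, 10), ca_table_factory(2),
                         neighbor_exclusion=0)
        assert not cm.values[0, 1]

    def test_neighbor_exclusion(self, ca_table_factory):
        cm = contact_map(self._traj([4.0] * 5, 5), ca_table_factory(2),
                         neighbor_exclusion=1)
        assert not cm.values[0, 1]  # residues 1 and 2 are sequence-adjacent

    def test_matches_brute_force_recount(self, ca_table_factory, rng):
        n, f = 6, 30
        coords = rng.uniform(40, 60, size=(f, n, 3))
        traj = Trajectory(coordinates=coords, box=BOX)
        atoms = ca_table_factory(n)
        cm = contact_map(traj, atoms, cutoff=5.0, occupancy=0.5,
                         neighbor_exclusion=0)
        for i, j in itertools.combinations(range(n), 2):
            frac = np.mean(np.linalg.norm(coords[:, i] - coords[:, j], axis=1)
                           <= 5.0)
            assert cm.values[i, j] == (frac >= 0.5)


class TestBuildNetwork:
    def _net(self, c01):
        cm = ContactMap(values=np.array([[False, True], [True, False]]),
                        node_ids=[1, 2], neighbor_exclusion=0)
        corr = CorrelationMatrix(values=np.array([[1.0, c01], [c01, 1.0]]),
                                 node_ids=[1, 2])
        return build_network(cm, corr)

    def test_perfect_correlation_zero_weight(self):
        assert self._net(1.0)[1][2]["weight"] == 0.0

    def test_hand_log(self):
        assert self._net(0.5)[1][2]["weight"] == pytest.approx(0.6931, abs=1e-4)

    def test_anticorrelation_uses_magnitude(self):
        assert self._net(-0.5)[1][2]["weight"] == pytest.approx(np.log(2.0))

    def test_no_contact_no_edge(self):
        cm = ContactMap(values=np.zeros((2, 2), dtype=bool), node_ids=[1, 2])
        corr = CorrelationMatrix(values=np.eye(2) * 0 + 0.9, node_ids=[1, 2])
        assert build_network(cm, corr).number_of_edges() == 0

    def test_zero_correlation_edge_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            g = self._net(0.0)
        assert g.number_of_edges() == 0


class TestPaths:
    def triangle(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("b", "c", weight=1.0)
        g.add_edge("a", "c", weight=3.0)
        return g

    def test_triangle_optimal(self):
        ps = optimal_path(self.triangle(), "a", "c")
        assert ps.optimal == ["a", "b", "c"]
        assert ps.optimal_length == pytest.approx(2.0)

    def test_triangle_boundary_strictly_excluded(self):
        """Direct a-c has length 3.0 = exactly 1.5x the optimum: the strict
        '< 50% deviation' bound excludes it."""
        ps = suboptimal_paths(self.triangle(), "a", "c", tolerance=0.5)
        assert [p for _, p in ps.suboptimal] == [["a", "b", "c"]]

    def test_single_edge_graph(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=0.7)
        ps = optimal_path(g, 1, 2)
        assert ps.optimal == [1, 2] and ps.optimal_length == pytest.approx(0.7)

    def test_unreachable_sink(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=1.0)
        g.add_node(3)
        with pytest.raises(ValueError, match="unreachable"):
            optimal_path(g, 1, 3)

    def test_symmetry_of_length(self, rng):
        for _ in range(10):
            g = random_weighted_graph(rng, 8)
            nodes = [n for n in g if g.degree(n)]
            if len(nodes) < 2:
                continue
            s, t = nodes[0], nodes[-1]
            try:
                a = optimal_path(g, s, t).optimal_length
                b = optimal_path(g, t, s).optimal_length
            except ValueError:
                continue
            assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("trial", range(25))
    def test_random_graphs_match_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        g = random_weighted_graph(rng, int(rng.integers(4, 13)))
        nodes = sorted(g)
        s, t = nodes[0], nodes[-1]
        if not nx.has_path(g, s, t):
            return
        all_paths = brute_force_paths(g, s, t)
        ps = suboptimal_paths(g, s, t, tolerance=0.5)
        assert ps.optimal_length == pytest.approx(all_paths[0][0], abs=1e-10)
        bound = 1.5 * all_paths[0][0]
        want = [(l, p) for l, p in all_paths if l < bound - 1e-12]
        got = ps.suboptimal
        assert len(got) == len(want)
        for (lw, pw), (lg, pg) in zip(want, got):
            assert lg == pytest.approx(lw, abs=1e-10)
        assert sorted(map(tuple, (p for _, p in want))) == \
            sorted(map(tuple, (p for _, p in got)))

    def test_tolerance_monotonicity(self, rng):
        g = random_weighted_graph(rng, 9, p=0.5)
        nodes = sorted(g)
        s, t = nodes[0], nodes[-1]
        if not nx.has_path(g, s, t):
            pytest.skip("disconnected draw")
        small = {tuple(p) for _, p in suboptimal_paths(g, s, t, 0.2).suboptimal}
        large = {tuple(p) for _, p in suboptimal_paths(g, s, t, 0.5).suboptimal}
        assert small <= large

    def test_label_permutation_equivariance(self, rng):
        g = random_weighted_graph(rng, 8, p=0.6)
        nodes = sorted(g)
        perm = {n: n + 100 for n in nodes}
        h = nx.relabel_nodes(g, perm)
        s, t = nodes[0], nodes[-1]
        if not nx.has_path(g, s, t):
            pytest.skip("disconnected draw")
        a = optimal_path(g, s, t)
        b = optimal_path(h, perm[s], perm[t])
        assert [perm[n] for n in a.optimal] == b.optimal
        assert a.optimal_length == pytest.approx(b.optimal_length)

    def test_cap_truncation_flagged(self):
        g = nx.complete_graph(8)
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        ps = suboptimal_paths(g, 0, 7, tolerance=2.0, cap=5)
        assert ps.truncated and len(ps.suboptimal) == 5


class TestCommunities:
    def test_two_cliques_bridge(self):
        g = nx.Graph()
        for off in (0, 8):
            for i, j in itertools.combinations(range(off, off + 8), 2):
                g.add_edge(i, j, weight=0.5, strength=0.6)
        g.add_edge(7, 8, weight=2.3, strength=0.1)
        part = communities(g)
        assert part.n_communities == 2
        assert len({part.membership[i] for i in range(8)}) == 1
        assert part.membership[0] != part.membership[8]

    def test_single_clique_one_community(self):
        g = nx.complete_graph(6)
        for u, v in g.edges:
            g[u][v].update(weight=0.5, strength=0.6)
        assert communities(g).n_communities == 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            communities(nx.Graph())

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_two_block_recovery(self, ca_table_factory, seed):
        """Planted block correlation 0.6 vs cross 0.1 at 1e4 frames is
        recovered with every node on the right side."""
        n = 16
        cov = two_block_covariance(n, 0.6, 0.1)
        traj = sample_harmonic_ensemble(
            HarmonicEnsembleSpec(n, np.zeros((n, 3)), cov, 10_000, seed=seed))
        corr = correlation_matrix(traj, ca_table_factory(n))
        net = build_network(two_block_contact_map(n), corr)
        part = communities(net)
        truth = np.array([0] * (n // 2) + [1] * (n // 2))
        got = np.array([part.membership[i] for i in sorted(part.membership)])
        acc = max((got == truth).mean(), (got == 1 - truth).mean())
        assert part.n_communities == 2 and acc == 1.0
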