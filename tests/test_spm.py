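"""Shortest-path-map construction against an independent brute-force oracle."""

import itertools

import numpy as np
import networkx as nx
import pytest

from allokin import (
    AverageDistanceMatrix,
    CorrelationMatrix,
    HarmonicNetworkSpec,
    Selection,
    Trajectory,
    average_distance_matrix,
    build_graph,
    correlation_matrix,
    make_harmonic_trajectory,
    path_between,
    reference_structure,
    shortest_path_map,
)
from allokin.spm import export_spm, read_edge_list
from allokin.synthetic_data import ca_chain_structure, two_state_loop_spec, make_two_state_trajectory


# ---------------------------------------------------------------------------
# independent oracle: Floyd-Warshall lengths + exhaustive path enumeration
# ---------------------------------------------------------------------------

def floyd_warshall(graph):
    nodes = sorted(graph.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v, data in graph.edges(data=True):
        d[pos[u], pos[v]] = d[pos[v], pos[u]] = data["length"]
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return nodes, d


def enumerate_best_path(graph, s, t, tol=1e-9):
    """Lexicographically smallest minimum-length simple path, by exhaustion."""
    best_len, best_path = np.inf, None
    stack = [(s, [s], 0.0)]
    while stack:
        u, path, length = stack.pop()
        if length > best_len + tol:
            continue
        if u == t:
            if length < best_len - tol or (length <= best_len + tol and
                                           (best_path is None or tuple(path) < tuple(best_path))):
                if length < best_len:
                    best_len = length
                best_path = list(path)
            continue
        for v in graph.neighbors(u):
            if v not in path:
                stack.append((v, path + [v], length + graph[u][v]["length"]))
    return best_path, best_len


def oracle_usage(graph, tol=1e-9):
    counts = {tuple(sorted(e)): 0 for e in graph.edges}
    lengths = {}
    for s, t in itertools.combinations(sorted(graph.nodes), 2):
        path, plen = enumerate_best_path(graph, s, t, tol)
        if path is None:
            continue
        lengths[(s, t)] = plen
        for a, b in zip(path[:-1], path[1:]):
            counts[tuple(sorted((a, b)))] += 1
    return counts, lengths


def random_graph(seed, n=10, p=0.4, weight_pool=None):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(1, n + 1))
    for u, v in itertools.combinations(range(1, n + 1), 2):
        if rng.random() < p:
            if weight_pool is None:
                w = float(rng.uniform(0.05, 2.0))
            else:
                w = float(rng.choice(weight_pool))
            g.add_edge(u, v, length=w)
    return g


# ---------------------------------------------------------------------------
# reference structure
# ---------------------------------------------------------------------------

class TestReferenceStructure:
    def test_identical_frames_returns_first(self, ca_structure):
        traj = Trajectory(ca_structure, ca_structure.coords[None].repeat(4, axis=0))
        idx, coords = reference_structure(traj)
        assert idx == 0
        assert np.allclose(coords, ca_structure.coords)

    def test_single_frame(self, ca_structure):
        traj = Trajectory(ca_structure, ca_structure.coords[None])
        idx, _ = reference_structure(traj)
        assert idx == 0

    def test_centroid_from_dominant_state(self):
        spec = two_state_loop_spec(p_a=0.8, seed=6)
        traj, labels, _ = make_two_state_trajectory(spec, 200)
        idx, _ = reference_structure(traj, epsilon=4.0)
        assert labels[idx] == 0  # member of the majority state


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

class TestCorrelationMatrix:
    def one_d_traj(self, disp_i, disp_j):
        # two sites far apart on x; displacements supplied along x
        topo = ca_chain_structure(np.array([[0.0, 0, 0], [100.0, 0, 0]]))
        frames = np.repeat(topo.coords[None], len(disp_i), axis=0)
        frames[:, 0, 0] += disp_i
        frames[:, 1, 0] += disp_j
        return Trajectory(topo, frames), topo.coords

    def test_identical_displacements_fully_correlated(self):
        traj, ref = self.one_d_traj([1, -1, 2, -2], [1, -1, 2, -2])
        c = correlation_matrix(traj, ref, superpose_frames=False)
        assert c.values[0, 1] == pytest.approx(1.0)

    def test_opposite_displacements_anticorrelated(self):
        traj, ref = self.one_d_traj([1, -1, 2, -2], [-1, 1, -2, 2])
        c = correlation_matrix(traj, ref, superpose_frames=False)
        assert c.values[0, 1] == pytest.approx(-1.0)

    def test_orthogonal_displacement_patterns_uncorrelated(self):
        traj, ref = self.one_d_traj([1, -1, 1, -1], [1, 1, -1, -1])
        c = correlation_matrix(traj, ref, superpose_frames=False)
        assert c.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_residue_flagged(self):
        traj, ref = self.one_d_traj([1, -1, 1, -1], [0, 0, 0, 0])
        c = correlation_matrix(traj, ref, superpose_frames=False)
        assert 2 in c.zero_variance  # residue 2 never moves
        assert c.values[0, 1] == 0.0
        assert c.values[1, 1] == 1.0

    def test_bounds_and_diagonal_always_valid(self, rng):
        topo = ca_chain_structure(rng.uniform(-20, 20, (6, 3)))
        frames = topo.coords[None] + rng.normal(0, 1.0, (30, 6, 3))
        c = correlation_matrix(Trajectory(topo, frames), topo.coords)
        assert np.abs(c.values).max() <= 1.0
        assert np.allclose(np.diag(c.values), 1.0)


class TestAverageDistanceMatrix:
    def test_static_structure(self, ca_structure):
        from scipy.spatial.distance import pdist, squareform

        traj = Trajectory(ca_structure, ca_structure.coords[None].repeat(3, axis=0))
        d = average_distance_matrix(traj)
        assert np.allclose(d.values, squareform(pdist(ca_structure.coords)))
        assert np.allclose(np.diag(d.values), 0.0)

    def test_arithmetic_mean_of_distances(self):
        topo = ca_chain_structure(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        frames = np.zeros((2, 2, 3))
        frames[0, 1, 0] = 1.0
        frames[1, 1, 0] = 3.0
        d = average_distance_matrix(Trajectory(topo, frames))
        assert d.values[0, 1] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def toy_matrices(c12, d12):
    c = np.array([[1.0, c12], [c12, 1.0]])
    d = np.array([[0.0, d12], [d12, 0.0]])
    return (CorrelationMatrix(c, np.array([1, 2])),
            AverageDistanceMatrix(d, np.array([1, 2])))


class TestBuildGraph:
    def test_perfect_correlation_zero_length(self):
        g = build_graph(*toy_matrices(1.0, 5.0))
        assert g[1][2]["length"] == pytest.approx(0.0)

    def test_distance_cutoff_excludes_edge(self):
        g = build_graph(*toy_matrices(0.9, 6.5))
        assert not g.has_edge(1, 2)

    def test_half_correlation_gives_ln2(self):
        g = build_graph(*toy_matrices(0.5, 4.0))
        assert g[1][2]["length"] == pytest.approx(np.log(2.0))

    def test_anticorrelation_counts_as_coupling(self):
        g = build_graph(*toy_matrices(-0.5, 4.0))
        assert g[1][2]["length"] == pytest.approx(np.log(2.0))

    def test_zero_correlation_no_edge(self):
        g = build_graph(*toy_matrices(0.0, 4.0))
        assert not g.has_edge(1, 2)

    def test_cutoff_monotonicity(self, rng):
        topo = ca_chain_structure(rng.uniform(-8, 8, (10, 3)))
        frames = topo.coords[None] + rng.normal(0, 0.5, (50, 10, 3))
        traj = Trajectory(topo, frames)
        c = correlation_matrix(traj, topo.coords)
        d = average_distance_matrix(traj)
        small = set(build_graph(c, d, cutoff=5.0).edges)
        large = set(build_graph(c, d, cutoff=9.0).edges)
        assert small <= large

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            build_graph(*toy_matrices(0.5, 4.0), cutoff=0.0)


# ---------------------------------------------------------------------------
# shortest-path accounting
# ---------------------------------------------------------------------------

class TestShortestPathMap:
    def test_path_graph_counts_match_oracle(self):
        g = nx.Graph()
        for u, v in [(1, 2), (2, 3), (3, 4)]:
            g.add_edge(u, v, length=1.0)
        spmap = shortest_path_map(g, keep_frac=0.0)
        counts, _ = oracle_usage(g)
        assert spmap.edge_usage == counts
        # middle edge carries the most traffic
        assert spmap.edge_usage[(2, 3)] == max(spmap.edge_usage.values())

    def test_disconnected_graph_all_zero(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 3])
        spmap = shortest_path_map(g, keep_frac=0.2)
        assert spmap.n_paths == 0
        assert spmap.retained.number_of_edges() == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_random_graphs_match_oracle(self, seed):
        # mix of generic float weights and tie-rich dyadic weights
        pool = None if seed % 2 == 0 else [0.5, 1.0]
        g = random_graph(seed, n=10 if seed < 10 else 12, weight_pool=pool)
        spmap = shortest_path_map(g, keep_frac=0.0)
        counts, lengths = oracle_usage(g)
        assert spmap.edge_usage == counts
        nodes, d = floyd_warshall(g)
        pos = {v: i for i, v in enumerate(nodes)}
        for (s, t), plen in lengths.items():
            assert d[pos[s], pos[t]] == pytest.approx(plen, abs=1e-9)

    def test_node_usage_conserved(self):
        g = random_graph(3, n=9)
        spmap = shortest_path_map(g, keep_frac=0.0)
        assert sum(spmap.node_usage.values()) == 2 * sum(spmap.edge_usage.values())

    def test_retained_map_invariant_to_log_base(self):
        # rescaling every length (change of log base) must not change the map
        g = random_graph(8, n=10)
        g2 = g.copy()
        for u, v in g2.edges:
            g2[u][v]["length"] = g[u][v]["length"] / np.log(10.0)
        a = shortest_path_map(g, keep_frac=0.2)
        b = shortest_path_map(g2, keep_frac=0.2)
        assert a.edge_usage == b.edge_usage
        assert set(a.retained.edges) == set(b.retained.edges)


class TestPathBetween:
    def weighted_square(self):
        g = nx.Graph()
        g.add_edge(1, 2, length=1.0)
        g.add_edge(2, 4, length=1.0)
        g.add_edge(1, 3, length=0.4)
        g.add_edge(3, 4, length=0.4)
        return g

    def test_singleton_source_equals_target(self):
        g = self.weighted_square()
        paths, best = path_between(g, [2], [2])
        assert best.length == 0.0 and best.nodes == (2,)

    def test_best_path_matches_hand_enumeration(self):
        g = self.weighted_square()
        _, best = path_between(g, [1], [4])
        assert best.nodes == (1, 3, 4)
        assert best.length == pytest.approx(0.8)

    def test_removing_best_path_edges_increases_length(self):
        g = self.weighted_square()
        _, best = path_between(g, [1], [4])
        g.remove_edge(1, 3)
        _, best2 = path_between(g, [1], [4])
        assert best2.length > best.length

    def test_no_connected_pair_warns_empty(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.warns(UserWarning, match="no connected"):
            paths, best = path_between(g, [1], [2])
        assert paths == [] and best is None


class TestExport:
    def test_round_trip_counts(self, tmp_path, ca_structure):
        g = random_graph(4, n=10)
        g = nx.relabel_nodes(g, {i: i for i in range(1, 11)})
        spmap = shortest_path_map(g, keep_frac=0.2)
        files = export_spm(spmap, ca_structure, str(tmp_path / "spm_"))
        back = read_edge_list(files["edges"])
        assert back == spmap.edge_usage

    def test_empty_map_writes_empty_files(self, tmp_path, ca_structure):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 3])
        spmap = shortest_path_map(g, keep_frac=0.2)
        files = export_spm(spmap, ca_structure, str(tmp_path / "spm_"))
        assert read_edge_list(files["edges"]) == {}
        script = open(files["script"]).read()
        assert "obj += [CYLINDER" not in script and "obj += [COLOR" not in script


class TestEndToEndCorrelationRecovery:
    def test_harmonic_correlation_recovery(self):
        # coupled-chain covariance: neighbours correlate ~0.5
        n = 20
        rng = np.random.default_rng(12)
        ref = np.stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)], axis=1)
        a = np.eye(3 * n)
        for i in range(n - 1):
            for k in range(3):
                a[3 * i + k, 3 * (i + 1) + k] = 0.5
        cov = 0.25 * (a @ a.T)
        spec = HarmonicNetworkSpec(ref, cov, seed=12)
        from allokin import ground_truth_correlation, make_harmonic_trajectory

        traj = make_harmonic_trajectory(spec, 20000)
        sampled = correlation_matrix(traj, spec.reference, superpose_frames=False)
        exact = ground_truth_correlation(spec)
        assert np.abs(sampled.values - exact.values).max() <= 0.05
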