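"""Shortest Path Maps (SPM) over residue correlation graphs.

Pipeline: (1) derive a reference structure as the centroid of the most
populated RMSD cluster of the Cα-aligned trajectory; (2) compute the
displacement correlation matrix

    C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨Δr_i²⟩ ⟨Δr_j²⟩),

where Δr is the Cα displacement from its reference position; (3) connect
residues whose Cα–Cα distance stays, on average, below a spatial cutoff
(6 Å by default) with edges of length

    l_ij = −ln |C_ij|,

so strongly (anti)correlated neighbouring residues are "short" to travel
through; (4) trace one shortest path between every residue pair and count
how often each edge and node is used; the most travelled subgraph above a
usage threshold is the final map — the backbone along which allosteric
communication is read.

Ties between equal-length paths are broken deterministically by taking the
lexicographically smallest node sequence (paths are written from the
lower-numbered endpoint), which path ranking itself never depends on: the
log base only rescales all lengths uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .trajectory_io import Selection, Structure, Trajectory, reduce, superpose

__all__ = [
    "CorrelationMatrix",
    "AverageDistanceMatrix",
    "SPMap",
    "PathResult",
    "reference_structure",
    "correlation_matrix",
    "average_distance_matrix",
    "build_graph",
    "shortest_path_map",
    "path_between",
    "export_spm",
    "read_edge_list",
    "write_square_matrix",
]

#: spatial contact cutoff on the average Cα–Cα distance, Å
DEFAULT_CUTOFF = 6.0
#: fraction of the maximum edge usage an edge must reach to stay in the map
DEFAULT_KEEP_FRAC = 0.2
#: relative tolerance when deciding whether two path lengths tie
_LENGTH_RTOL = 1e-9


@dataclass
class CorrelationMatrix:
    """Cα displacement correlations, C_ii = 1, |C_ij| ≤ 1."""

    values: np.ndarray
    resids: np.ndarray
    zero_variance: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        n = self.resids.size
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square over the residue map")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(self.values).max() > 1.0 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = np.clip(self.values, -1.0, 1.0)
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("correlation diagonal must be 1")


@dataclass
class AverageDistanceMatrix:
    """Mean inter-Cα distances over the trajectory, Å."""

    values: np.ndarray
    resids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        n = self.resids.size
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square over the residue map")
        if self.values.min() < 0 or np.any(np.diag(self.values) != 0.0):
            raise ValueError("distances must be non-negative with zero diagonal")


@dataclass
class SPMap:
    """Edge/node usage counts over all-pairs shortest paths.

    ``node_usage[v]`` is the summed usage of the edges incident to ``v``
    (so Σ_v node_usage = 2 Σ_e edge_usage).  ``retained`` holds the
    subgraph of edges whose usage reaches ``keep_frac`` of the maximum.
    """

    edge_usage: dict
    node_usage: dict
    keep_frac: float
    threshold: float
    retained: nx.Graph
    n_paths: int
    edge_length: dict = field(default_factory=dict)


@dataclass
class PathResult:
    source: int
    target: int
    nodes: tuple
    length: float


# ---------------------------------------------------------------------------
# reference structure & matrices
# ---------------------------------------------------------------------------

def reference_structure(traj: Trajectory, epsilon: float = 2.0,
                        max_cluster_frames: int = 2000) -> tuple[int, np.ndarray]:
    """Most-representative frame: centroid of the largest RMSD cluster.

    Frames are superposed on Cα, hierarchically clustered on pairwise Cα
    RMSD with merge cutoff ``epsilon`` (Å), and the member of the most
    populated cluster minimising the summed RMSD to its cluster mates is
    returned as ``(frame_index, full-atom coordinates)``.  Very long
    trajectories are strided down to ``max_cluster_frames`` for the O(F²)
    clustering; the centroid is then chosen among the strided frames.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if traj.n_frames == 1:
        return 0, traj.coords[0].copy()
    fitted = superpose(traj, 0, Selection.ca())
    ca = reduce(fitted, Selection.ca())
    stride = max(1, int(np.ceil(ca.n_frames / max_cluster_frames)))
    frame_ids = np.arange(0, ca.n_frames, stride)
    flat = ca.coords[frame_ids].reshape(frame_ids.size, -1)

    from .loop_clustering import _cluster_flat_frames

    labels, _, centroids, _ = _cluster_flat_frames(flat, epsilon, "average",
                                                   n_sites=ca.n_atoms)
    best = int(frame_ids[centroids[0]])
    return best, fitted.coords[best].copy()


def correlation_matrix(traj: Trajectory, reference: np.ndarray | int | None = None,
                       sel: Selection | None = None, superpose_frames: bool = True) -> CorrelationMatrix:
    """Displacement correlation of each residue pair w.r.t. a reference.

    ``reference`` is a frame index, explicit full-topology coordinates, or
    ``None`` (derive via :func:`reference_structure`).  Frames are
    superposed onto the reference on Cα unless ``superpose_frames`` is
    False (for trajectories generated or already prepared in the reference
    frame).  Residues with zero total displacement are flagged and their
    off-diagonal correlations set to zero.
    """
    if traj.n_frames < 2:
        raise ValueError("correlation needs at least 2 frames")
    sel = sel or Selection.ca()
    if reference is None:
        _, reference = reference_structure(traj)
    elif isinstance(reference, (int, np.integer)):
        reference = traj.coords[int(reference)].copy()
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise ValueError("reference must cover the full topology")
    if superpose_frames:
        traj = superpose(traj, reference, sel)
    idx = sel.indices(traj.topology)
    resids = traj.topology.resids[idx]
    disp = traj.coords[:, idx] - reference[idx]
    f = traj.n_frames
    inner = np.einsum("fia,fja->ij", disp, disp) / f
    msd = np.diag(inner).copy()
    zero = msd <= 0.0
    denom = np.sqrt(np.outer(np.where(zero, 1.0, msd), np.where(zero, 1.0, msd)))
    values = inner / denom
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    np.fill_diagonal(values, 1.0)
    np.clip(values, -1.0, 1.0, out=values)
    return CorrelationMatrix(values=values, resids=resids,
                             zero_variance=resids[zero],
                             meta={"n_frames": f, "superposed": superpose_frames})


def average_distance_matrix(traj: Trajectory, sel: Selection | None = None) -> AverageDistanceMatrix:
    """Mean Cα–Cα distance matrix (rotation-invariant, no fitting)."""
    from scipy.spatial.distance import pdist, squareform

    sel = sel or Selection.ca()
    idx = sel.indices(traj.topology)
    resids = traj.topology.resids[idx]
    coords = traj.coords[:, idx]
    acc = np.zeros(idx.size * (idx.size - 1) // 2)
    for frame in coords:
        acc += pdist(frame)
    return AverageDistanceMatrix(squareform(acc / traj.n_frames), resids)


# ---------------------------------------------------------------------------
# graph construction and shortest-path accounting
# ---------------------------------------------------------------------------

def build_graph(corr: CorrelationMatrix, dist: AverageDistanceMatrix,
                cutoff: float = DEFAULT_CUTOFF) -> nx.Graph:
    """Residue graph: edges where ⟨d_ij⟩ < cutoff, length −ln |C_ij|.

    Pairs with C_ij = 0 get no edge (infinite length); anticorrelated pairs
    count as coupled through the absolute value.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if corr.resids.shape != dist.resids.shape or np.any(corr.resids != dist.resids):
        raise ValueError("correlation and distance matrices cover different residues")
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in corr.resids)
    n = corr.resids.size
    for i in range(n):
        for j in range(i + 1, n):
            c = abs(corr.values[i, j])
            if dist.values[i, j] < cutoff and c > 0.0:
                g.add_edge(int(corr.resids[i]), int(corr.resids[j]),
                           length=float(-np.log(c)), correlation=float(corr.values[i, j]),
                           distance=float(dist.values[i, j]))
    return g


def _adjacency(graph: nx.Graph):
    nodes = sorted(graph.nodes)
    pos = {v: k for k, v in enumerate(nodes)}
    nbrs: list[list[tuple[int, float]]] = [[] for _ in nodes]
    for u, v, data in graph.edges(data=True):
        w = float(data["length"])
        if w < 0:
            raise ValueError("negative edge length")
        nbrs[pos[u]].append((pos[v], w))
        nbrs[pos[v]].append((pos[u], w))
    for lst in nbrs:
        lst.sort()
    return nodes, pos, nbrs


def _all_pairs_lengths(nodes, nbrs) -> np.ndarray:
    import heapq

    n = len(nodes)
    dmat = np.full((n, n), np.inf)
    for s in range(n):
        dist = dmat[s]
        dist[s] = 0.0
        seen = np.zeros(n, dtype=bool)
        heap = [(0.0, s)]
        while heap:
            du, u = heapq.heappop(heap)
            if seen[u]:
                continue
            seen[u] = True
            for v, w in nbrs[u]:
                alt = du + w
                if alt < dist[v]:
                    dist[v] = alt
                    heapq.heappush(heap, (alt, v))
    return dmat


def _lexicographic_path(s: int, t: int, nbrs, dmat: np.ndarray) -> list[int]:
    """Greedy walk from s to t choosing the smallest next node on a shortest path."""
    path = [s]
    u = s
    total = dmat[s, t]
    while u != t:
        du = dmat[s, u]
        nxt = None
        for v, w in nbrs[u]:  # nbrs sorted by node index
            if abs(du + w + dmat[v, t] - total) <= _LENGTH_RTOL * (1.0 + total):
                nxt = v
                break
        if nxt is None:  # numerical dead end; should not happen
            raise RuntimeError("shortest-path reconstruction failed")
        path.append(nxt)
        u = nxt
    return path


def shortest_path_map(graph: nx.Graph, keep_frac: float = DEFAULT_KEEP_FRAC) -> SPMap:
    """Count edge/node usage over one shortest path per connected pair.

    For every unordered node pair in the same component one shortest path
    is traced (lexicographic tie-break) and each of its edges credited.
    Edges with usage ≥ ``keep_frac`` × max usage form the retained map.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("graph needs at least 2 nodes")
    if not 0.0 <= keep_frac <= 1.0:
        raise ValueError("keep_frac must be in [0, 1]")
    nodes, pos, nbrs = _adjacency(graph)
    dmat = _all_pairs_lengths(nodes, nbrs)
    edge_usage: dict[tuple[int, int], int] = {
        tuple(sorted((u, v))): 0 for u, v in graph.edges
    }
    n = len(nodes)
    n_paths = 0
    for si in range(n):
        for ti in range(si + 1, n):
            if not np.isfinite(dmat[si, ti]):
                continue
            n_paths += 1
            path = _lexicographic_path(si, ti, nbrs, dmat)
            for a, b in zip(path[:-1], path[1:]):
                key = tuple(sorted((nodes[a], nodes[b])))
                edge_usage[key] += 1
    node_usage = {v: 0 for v in graph.nodes}
    for (u, v), c in edge_usage.items():
        node_usage[u] += c
        node_usage[v] += c
    max_usage = max(edge_usage.values(), default=0)
    threshold = keep_frac * max_usage
    retained = nx.Graph()
    for (u, v), c in edge_usage.items():
        if max_usage > 0 and c >= threshold and c > 0:
            retained.add_edge(u, v, usage=c, length=graph[u][v]["length"])
    lengths = {tuple(sorted((u, v))): float(d["length"])
               for u, v, d in graph.edges(data=True)}
    return SPMap(edge_usage=edge_usage, node_usage=node_usage,
                 keep_frac=keep_frac, threshold=threshold,
                 retained=retained, n_paths=n_paths, edge_length=lengths)


def path_between(graph: nx.Graph, source: Selection | list, target: Selection | list):
    """Shortest paths from every source residue to every target residue.

    Returns ``(paths, best)`` where ``paths`` holds one
    :class:`PathResult` per connected (source, target) pair and ``best``
    is the minimum-length one (``None`` when no pair is connected; a
    warning is emitted instead of an error).
    """
    import warnings

    src = _resolve_nodes(graph, source)
    tgt = _resolve_nodes(graph, target)
    nodes, pos, nbrs = _adjacency(graph)
    dmat = _all_pairs_lengths(nodes, nbrs)
    results: list[PathResult] = []
    for s in src:
        for t in tgt:
            if s == t:
                results.append(PathResult(s, t, (s,), 0.0))
                continue
            si, ti = pos[s], pos[t]
            if not np.isfinite(dmat[si, ti]):
                continue
            a, b = (si, ti) if nodes[si] <= nodes[ti] else (ti, si)
            p = _lexicographic_path(a, b, nbrs, dmat)
            nodes_seq = tuple(nodes[i] for i in p)
            if nodes_seq[0] != s:
                nodes_seq = nodes_seq[::-1]
            results.append(PathResult(s, t, nodes_seq, float(dmat[si, ti])))
    if not results:
        warnings.warn("no connected source-target pair", stacklevel=2)
        return [], None
    best = min(results, key=lambda r: (r.length, r.nodes))
    return results, best


def _resolve_nodes(graph: nx.Graph, sel) -> list[int]:
    if isinstance(sel, Selection):
        resids = sel.resid_list()
        if resids is None:
            resids = sorted(graph.nodes)
    else:
        resids = [int(r) for r in sel]
    nodes = [r for r in resids if r in graph]
    if not nodes:
        raise ValueError("selection matches no graph nodes")
    return nodes


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_spm(spmap: SPMap, structure: Structure, prefix) -> dict:
    """Write the map as plain-text artifacts plus a PyMOL drawing script.

    Files: ``<prefix>edges.txt`` (edge list with usage counts and lengths),
    ``<prefix>nodes.tsv`` (per-node usage), ``<prefix>draw.py`` (spheres at
    Cα positions, cylinders along retained edges, width ∝ usage).
    """
    prefix = str(prefix)
    edges_path = prefix + "edges.txt"
    nodes_path = prefix + "nodes.tsv"
    script_path = prefix + "draw.py"

    with open(edges_path, "w") as fh:
        fh.write("# residue_i residue_j usage length retained\n")
        for (u, v), c in sorted(spmap.edge_usage.items()):
            kept = int(spmap.retained.has_edge(u, v))
            fh.write(f"{u} {v} {c} {_edge_length(spmap, u, v):.17g} {kept}\n")

    with open(nodes_path, "w") as fh:
        fh.write("residue\tusage\tretained\n")
        for v in sorted(spmap.node_usage):
            fh.write(f"{v}\t{spmap.node_usage[v]}\t{int(v in spmap.retained)}\n")

    ca_idx = Selection.ca().indices(structure)
    ca_pos = {int(structure.resids[i]): structure.coords[i] for i in ca_idx}
    max_usage = max(spmap.edge_usage.values(), default=1) or 1
    with open(script_path, "w") as fh:
        fh.write("# PyMOL CGO script drawing the shortest path map\n")
        fh.write("from pymol.cgo import CYLINDER, SPHERE, COLOR\nfrom pymol import cmd\nobj = []\n")
        for v in sorted(spmap.retained.nodes):
            if v in ca_pos:
                x, y, z = ca_pos[v]
                fh.write(f"obj += [COLOR, 0.1, 0.1, 0.6, SPHERE, {x:.3f}, {y:.3f}, {z:.3f}, 0.8]\n")
        for (u, v), c in sorted(spmap.edge_usage.items()):
            if not spmap.retained.has_edge(u, v) or u not in ca_pos or v not in ca_pos:
                continue
            w = 0.2 + 0.6 * c / max_usage
            (x1, y1, z1), (x2, y2, z2) = ca_pos[u], ca_pos[v]
            fh.write(
                f"obj += [CYLINDER, {x1:.3f}, {y1:.3f}, {z1:.3f}, "
                f"{x2:.3f}, {y2:.3f}, {z2:.3f}, {w:.3f}, "
                "0.5, 0.7, 0.9, 0.5, 0.7, 0.9]\n"
            )
        fh.write("cmd.load_cgo(obj, 'spm')\n")
    return {"edges": edges_path, "nodes": nodes_path, "script": script_path}


def _edge_length(spmap: SPMap, u: int, v: int) -> float:
    return float(spmap.edge_length.get(tuple(sorted((u, v))), float("nan")))


def read_edge_list(path) -> dict[tuple[int, int], int]:
    """Read back usage counts from an exported edge list."""
    out: dict[tuple[int, int], int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            u, v, c = line.split()[:3]
            out[(int(u), int(v))] = int(c)
    return out


def write_square_matrix(values: np.ndarray, resids: np.ndarray, path, kind: str) -> None:
    """Plain-text square matrix (correlation or average distance)."""
    with open(path, "w") as fh:
        fh.write(f"# allokin matrix kind={kind}\n")
        fh.write("# residues " + " ".join(str(r) for r in resids) + "\n")
        np.savetxt(fh, values, fmt="%.17g")
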