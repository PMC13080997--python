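"""Loop-conformation clustering of MD trajectories.

Four-step protocol for monitoring the conformational states of a flexible
loop (designed around loop L5 of the kinesin-5 motor domain, residues
116–134, flanked by helix α2):

1. strip the trajectory to its backbone (N, CA, C, O) and align every
   frame to the backbone of the first frame;
2. align on the residues that keep a stable secondary structure across all
   catalytic states (computed by :func:`stable_ss_mask` or user-supplied)
   and compute an averaged structure;
3. fit the frames to an anchor subselection of the flanking helix
   (residues 111–116 and 135–140 by default) of that averaged structure
   and retain only the backbone of the loop window (111–140);
4. hierarchical agglomerative clustering on the pairwise RMSD of the
   retained coordinates, merging until the closest pair of clusters is
   further apart than ε (5 Å by default).

The pairwise RMSD is deliberately computed *without* per-pair
re-superposition: frames are already in the anchor frame, so a loop that
swings away from the helix scores a large RMSD even if its internal shape
is unchanged — this is what separates "docked" from "undocked"
conformations rather than shape-only differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import (
    Selection,
    Structure,
    Trajectory,
    average_structure,
    reduce,
    rmsd,
    superpose,
)

__all__ = [
    "ClusteringProtocolConfig",
    "ClusterResult",
    "stable_ss_mask",
    "stable_residues_from_assignments",
    "protocol_transform",
    "hier_cluster",
    "compare_representatives",
    "run_protocol",
]

_LINKAGES = ("average", "single", "complete")


@dataclass
class ClusteringProtocolConfig:
    """Parameters of the loop-clustering protocol.

    Defaults follow the kinesin-5 L5 analysis: loop window 111–140
    (α2 helix + L5), anchor 111–116 ∪ 135–140, ε = 5 Å, average linkage.
    """

    loop: Selection = field(default_factory=lambda: Selection.backbone([(111, 140)]))
    anchor: Selection = field(default_factory=lambda: Selection.backbone([(111, 116), (135, 140)]))
    stable_ss: Selection | None = None
    epsilon: float = 5.0
    linkage: str = "average"
    stability_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"linkage must be one of {_LINKAGES}")
        if not 0.0 < self.stability_fraction <= 1.0:
            raise ValueError("stability_fraction must be in (0, 1]")


@dataclass
class ClusterResult:
    """Labels (0 = most populated cluster), populations, centroid frames."""

    labels: np.ndarray
    populations: np.ndarray
    centroid_frames: list[int]
    rmsd_summary: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.populations.size


# ---------------------------------------------------------------------------
# secondary-structure stability mask
# ---------------------------------------------------------------------------

def stable_residues_from_assignments(assignments: list[np.ndarray], resids: np.ndarray,
                                     stability_fraction: float) -> list[int]:
    """Residues assigned helix/strand in ≥ the given fraction of frames of
    *every* assignment series.

    ``assignments`` holds one (F, n_res) array of single-letter codes per
    trajectory ('H' helix, 'E' strand, anything else coil).
    """
    keep = np.ones(len(resids), dtype=bool)
    for series in assignments:
        structured = np.isin(series, ("H", "E", "G", "I"))
        keep &= structured.mean(axis=0) >= stability_fraction
    return [int(r) for r in np.asarray(resids)[keep]]


def stable_ss_mask(trajs: list[Trajectory], stability_fraction: float = 0.75) -> Selection:
    """Selection of residues with stable secondary structure in every input.

    Assignment uses the DSSP implementation shipped with MDAnalysis, which
    needs the full backbone (N, CA, C, O) — a Cα-only trajectory raises
    with a hint to keep the backbone.
    """
    if not trajs:
        raise ValueError("no trajectories given")
    assignments = []
    common: set[int] | None = None
    for traj in trajs:
        names = set(np.char.upper(traj.topology.names.astype(str)))
        if not {"N", "CA", "C", "O"} <= names:
            raise ValueError(
                "secondary-structure assignment needs backbone atoms N/CA/C/O; "
                "keep the backbone when reducing the trajectory"
            )
        series, resids = _dssp_series(traj)
        assignments.append((series, resids))
        common = set(resids) if common is None else common & set(resids)
    resids = np.array(sorted(common))
    per_traj = []
    for series, tr_resids in assignments:
        col = {int(r): k for k, r in enumerate(tr_resids)}
        per_traj.append(series[:, [col[int(r)] for r in resids]])
    stable = stable_residues_from_assignments(per_traj, resids, stability_fraction)
    if not stable:
        raise ValueError("no residue is stably structured in every trajectory")
    return Selection.from_resids(stable)


def _dssp_series(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    from MDAnalysis.analysis.dssp import DSSP
    from MDAnalysis.coordinates.memory import MemoryReader

    from .trajectory_io import _as_universe

    bb = reduce(traj, Selection.backbone())
    u = _as_universe(bb.topology)
    u.load_new(bb.coords.astype(np.float32), format=MemoryReader)
    result = DSSP(u, guess_hydrogens=True).run()
    series = np.asarray(result.results.dssp)
    resids = np.unique(bb.topology.resids)
    return series, resids


# ---------------------------------------------------------------------------
# protocol steps
# ---------------------------------------------------------------------------

def protocol_transform(traj: Trajectory, config: ClusteringProtocolConfig) -> tuple[Trajectory, np.ndarray]:
    """Steps 1–3: strip, align, average, anchor-fit, retain the loop window.

    Returns the backbone-only loop trajectory expressed in the
    anchor-fitted frame together with the averaged structure (full
    backbone) used for the fit.
    """
    if traj.n_frames < 2:
        raise ValueError("protocol needs at least 2 frames")
    backbone = reduce(traj, Selection.backbone())
    step1 = superpose(backbone, 0, Selection.backbone())

    stable = config.stable_ss
    if stable is None:
        stable = stable_ss_mask([step1], config.stability_fraction)
    stable_bb = Selection(residues=stable.residues, atoms=Selection.backbone().atoms)
    step2 = superpose(step1, 0, stable_bb)
    avg = average_structure(step2)

    fitted = superpose(step2, avg, config.anchor)
    reduced = reduce(fitted, config.loop)
    return reduced, avg


def _pairwise_rmsd_condensed(flat: np.ndarray, n_sites: int) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(flat) / np.sqrt(n_sites)


def _cluster_flat_frames(flat: np.ndarray, epsilon: float, linkage: str, n_sites: int):
    """Agglomerative clustering of flattened frames on no-refit RMSD.

    Returns ``(labels, populations, centroid_frames, square_rmsd)`` with
    clusters relabelled by decreasing population (ties by first frame) and
    centroids chosen as the member minimising the summed RMSD to its
    cluster mates.
    """
    from scipy.cluster.hierarchy import fcluster
    from scipy.cluster.hierarchy import linkage as scipy_linkage
    from scipy.spatial.distance import squareform

    f = flat.shape[0]
    condensed = _pairwise_rmsd_condensed(flat, n_sites)
    if f == 1:
        return np.zeros(1, dtype=int), np.array([1.0]), [0], np.zeros((1, 1))
    z = scipy_linkage(condensed, method=linkage)
    raw = fcluster(z, t=epsilon, criterion="distance")
    # relabel by decreasing population, deterministic tie-break on first frame
    ids, counts = np.unique(raw, return_counts=True)
    first = {cid: int(np.flatnonzero(raw == cid)[0]) for cid in ids}
    order = sorted(ids, key=lambda cid: (-counts[list(ids).index(cid)], first[cid]))
    remap = {cid: k for k, cid in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    populations = np.array([np.sum(labels == k) for k in range(len(ids))]) / f

    sq = squareform(condensed)
    centroids = []
    for k in range(len(ids)):
        members = np.flatnonzero(labels == k)
        sums = sq[np.ix_(members, members)].sum(axis=1)
        centroids.append(int(members[int(np.argmin(sums))]))
    return labels, populations, centroids, sq


def hier_cluster(reduced: Trajectory, epsilon: float = 5.0, linkage: str = "average") -> ClusterResult:
    """Step 4: agglomerative RMSD clustering of the prepared loop frames.

    Merging proceeds until the linkage distance of the closest cluster
    pair exceeds ε; the pairwise RMSD uses the coordinates as-is (already
    anchor-fitted), with no per-pair re-superposition.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if reduced.n_frames < 2:
        raise ValueError("clustering needs at least 2 frames")
    flat = reduced.coords.reshape(reduced.n_frames, -1)
    labels, populations, centroids, sq = _cluster_flat_frames(
        flat, epsilon, linkage, n_sites=reduced.n_atoms
    )
    within = []
    for k in range(populations.size):
        members = np.flatnonzero(labels == k)
        if members.size > 1:
            block = sq[np.ix_(members, members)]
            within.append(block[~np.eye(members.size, dtype=bool)].mean())
    n = sq.shape[0]
    summary = {
        "mean_within_cluster_rmsd": float(np.mean(within)) if within else 0.0,
        "mean_pairwise_rmsd": float(sq.sum() / (n * (n - 1))) if n > 1 else 0.0,
        "max_pairwise_rmsd": float(sq.max()),
    }
    return ClusterResult(labels=labels, populations=populations,
                         centroid_frames=centroids, rmsd_summary=summary)


def compare_representatives(a: np.ndarray, b: np.ndarray, fit: bool = True) -> float:
    """Fitted RMSD between two cluster-centroid coordinate sets, Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"representative shapes differ: {a.shape} vs {b.shape}")
    return rmsd(a, b, fit=fit)


def run_protocol(traj: Trajectory, config: ClusteringProtocolConfig | None = None) -> tuple[ClusterResult, Trajectory]:
    """Full protocol: transform (steps 1–3) then cluster (step 4)."""
    config = config or ClusteringProtocolConfig()
    reduced, _ = protocol_transform(traj, config)
    result = hier_cluster(reduced, config.epsilon, config.linkage)
    return result, reduced
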