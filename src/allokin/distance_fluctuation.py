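"""Distance-fluctuation (DF) matrices and state-to-state differences.

The DF score of a residue pair is the variance of their inter-Cα distance
over the trajectory,

    DF_ij = ⟨(d_ij − ⟨d_ij⟩)²⟩   [Å²],

a rotation/translation-invariant measure of how *coordinated* the pair's
motion is: low DF means the two residues move as one rigid unit and are
taken to be allosterically coupled.  No superposition is performed — the
statistic only involves internal distances.

ΔDF matrices subtract the DF matrix of an initial catalytic state from
that of a final state; positive entries mean the pair lost coordination
across the transition, negative entries mean it gained coordination.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import Selection, Trajectory

__all__ = [
    "DFMatrix",
    "DeltaDFMatrix",
    "compute_df",
    "delta_df",
    "residue_profile",
    "region_summary",
    "write_matrix",
    "read_matrix",
]


@dataclass
class DFMatrix:
    """Symmetric non-negative N×N matrix of distance variances in Å²."""

    scores: np.ndarray
    resids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        n = self.resids.size
        if self.scores.shape != (n, n):
            raise ValueError("scores must be square over the residue map")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("DF scores must be finite")
        if not np.allclose(self.scores, self.scores.T, atol=1e-10):
            raise ValueError("DF matrix must be symmetric")
        if np.any(np.diag(self.scores) != 0.0):
            raise ValueError("DF diagonal must be zero")
        if self.scores.min() < -1e-10:
            raise ValueError("DF scores must be non-negative")
        self.scores[self.scores < 0] = 0.0

    def index_of(self, resid: int) -> int:
        hits = np.flatnonzero(self.resids == resid)
        if hits.size != 1:
            raise KeyError(f"residue {resid} not in matrix residue map")
        return int(hits[0])


@dataclass
class DeltaDFMatrix:
    """Elementwise final-state minus initial-state DF difference, Å²."""

    deltas: np.ndarray
    resids: np.ndarray
    final_label: str = "final"
    initial_label: str = "initial"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        n = self.resids.size
        if self.deltas.shape != (n, n):
            raise ValueError("deltas must be square over the residue map")
        if np.any(np.diag(self.deltas) != 0.0):
            raise ValueError("ΔDF diagonal must be zero")

    def index_of(self, resid: int) -> int:
        hits = np.flatnonzero(self.resids == resid)
        if hits.size != 1:
            raise KeyError(f"residue {resid} not in matrix residue map")
        return int(hits[0])


def _one_atom_per_residue(traj: Trajectory, sel: Selection) -> tuple[np.ndarray, np.ndarray]:
    idx = sel.indices(traj.topology)
    resids = traj.topology.resids[idx]
    if np.unique(resids).size != resids.size:
        raise ValueError(
            "selection yields more than one atom for some residue; DF needs "
            "exactly one site (e.g. the Cα) per residue"
        )
    return idx, resids


def _distance_moments(coords: np.ndarray, chunk: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Mean and mean-square of all pairwise distances, streamed over frames."""
    from scipy.spatial.distance import pdist

    f, n = coords.shape[:2]
    s1 = np.zeros(n * (n - 1) // 2)
    s2 = np.zeros_like(s1)
    for start in range(0, f, chunk):
        for frame in coords[start:start + chunk]:
            d = pdist(frame)
            s1 += d
            s2 += d * d
    return s1 / f, s2 / f


def compute_df(traj: Trajectory, sel: Selection | None = None,
               replica_mode: str = "pooled", ddof: int = 0) -> DFMatrix:
    """Distance-fluctuation matrix of a (meta)trajectory.

    Parameters
    ----------
    sel
        One atom per residue; defaults to all Cα.
    replica_mode
        ``"pooled"`` treats the concatenated metatrajectory as one sample
        (the default); ``"per_replica_mean"`` averages the DF matrices of
        the individual replicas, which discards the between-replica
        variance component (pooled ≥ per-replica mean, by the law of total
        variance).
    ddof
        0 gives the population variance matching the expectation form of
        the definition; 1 the unbiased sample variance.
    """
    sel = sel or Selection.ca()
    if traj.n_frames < 2:
        raise ValueError("DF needs at least 2 frames")
    if replica_mode not in ("pooled", "per_replica_mean"):
        raise ValueError(f"unknown replica_mode {replica_mode!r}")
    idx, resids = _one_atom_per_residue(traj, sel)
    coords = traj.coords[:, idx]
    n = idx.size

    def block_var(block: np.ndarray) -> np.ndarray:
        f = block.shape[0]
        m1, m2 = _distance_moments(block)
        var = m2 - m1 * m1
        if ddof:
            if f <= ddof:
                raise ValueError("not enough frames for the requested ddof")
            var = var * f / (f - ddof)
        return var

    if replica_mode == "pooled":
        condensed = block_var(coords)
    else:
        parts = [block_var(coords[sl]) for sl in traj.replica_slices()]
        condensed = np.mean(parts, axis=0)

    from scipy.spatial.distance import squareform

    scores = squareform(np.clip(condensed, 0.0, None))
    return DFMatrix(scores=scores, resids=resids, meta={
        "replica_mode": replica_mode,
        "n_frames": traj.n_frames,
        "n_replicas": len(traj.replica_bounds),
        "ddof": ddof,
    })


def delta_df(final: DFMatrix, initial: DFMatrix) -> DeltaDFMatrix:
    """ΔDF = DF(final) − DF(initial), elementwise.

    Positive entries flag pairs that lost coordination over the
    transition; negative entries flag gains.
    """
    if final.resids.shape != initial.resids.shape or np.any(final.resids != initial.resids):
        raise ValueError("DF matrices cover different residue maps")
    return DeltaDFMatrix(
        deltas=final.scores - initial.scores,
        resids=final.resids.copy(),
        final_label=str(final.meta.get("state", "final")),
        initial_label=str(initial.meta.get("state", "initial")),
    )


def residue_profile(delta: DeltaDFMatrix | DFMatrix, residue: int) -> np.ndarray:
    """Row of the matrix for one residue — its coupling change to everyone.

    Suitable for projection onto a structure (e.g. colouring every residue
    by its ΔDF against a single anchor residue).
    """
    i = delta.index_of(residue)
    matrix = delta.deltas if isinstance(delta, DeltaDFMatrix) else delta.scores
    return matrix[i].copy()


def region_summary(matrix: DFMatrix | DeltaDFMatrix, region_a: Selection,
                   region_b: Selection | None = None, statistic: str = "mean") -> float:
    """Aggregate matrix entries over the region-A × region-B block.

    With a single region the summary is over its internal pairs (diagonal
    excluded).  ``statistic`` is ``"mean"`` or ``"median"``.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    values = matrix.deltas if isinstance(matrix, DeltaDFMatrix) else matrix.scores
    ma = region_a.residue_mask(matrix.resids)
    mb = ma if region_b is None else region_b.residue_mask(matrix.resids)
    block = values[np.ix_(ma, mb)]
    if np.array_equal(ma, mb):
        iu = ~np.eye(block.shape[0], dtype=bool)
        entries = block[iu]
    else:
        entries = block.ravel()
    if entries.size == 0:
        raise ValueError("region block is empty")
    return float(np.mean(entries) if statistic == "mean" else np.median(entries))


# ---------------------------------------------------------------------------
# plain-text matrix files
# ---------------------------------------------------------------------------

def write_matrix(obj: DFMatrix | DeltaDFMatrix, path) -> None:
    """Whitespace-delimited square matrix with a residue-id header.

    Values are printed with 17 significant digits so a read-back is
    bit-identical.
    """
    if isinstance(obj, DeltaDFMatrix):
        kind, values = "ddf", obj.deltas
        extra = f" final={obj.final_label} initial={obj.initial_label}"
    else:
        kind, values = "df", obj.scores
        extra = ""
    with open(path, "w") as fh:
        fh.write(f"# allokin matrix kind={kind}{extra}\n")
        fh.write("# residues " + " ".join(str(r) for r in obj.resids) + "\n")
        np.savetxt(fh, values, fmt="%.17g")


def read_matrix(path) -> DFMatrix | DeltaDFMatrix:
    with open(path) as fh:
        head = fh.readline().split()
        if not head or head[0] != "#" or not head[1].startswith("allokin"):
            raise ValueError(f"{path} is not an allokin matrix file")
        fields = dict(tok.split("=", 1) for tok in head[2:] if "=" in tok)
        kind = fields.get("kind", "df")
        res_line = fh.readline().split()
        resids = np.array([int(r) for r in res_line[2:]])
        values = np.loadtxt(io.StringIO(fh.read()), ndmin=2)
    if kind == "ddf":
        return DeltaDFMatrix(values, resids,
                             final_label=fields.get("final", "final"),
                             initial_label=fields.get("initial", "initial"))
    return DFMatrix(values, resids)
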