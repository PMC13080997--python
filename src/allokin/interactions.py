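"""Per-frame noncovalent interaction metrics and spatial distributions.

Geometric criteria for π-stacking, salt bridges and hydrogen bonds, each
reported as a time series plus an *occupancy* — the fraction of frames in
which the criterion holds.  The default thresholds (5.5 Å / 30° stacking,
4.0 Å salt bridge, 3.5 Å / 135° hydrogen bond) are conventional values
for heavy-atom MD analyses; every one of them is a parameter and is
recorded in the result so the criterion a number was computed under is
never ambiguous.

Also here: radial distribution functions around a reference selection and
3-D occupancy density grids with a Jaccard-like overlap score
Σ min(a, b) / Σ max(a, b) for comparing where a ligand sits in two
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import Selection, Trajectory

__all__ = [
    "InteractionSeries",
    "RDFProfile",
    "GridSpec",
    "DensityGrid",
    "pi_stack_series",
    "salt_bridge_series",
    "hbond_series",
    "rdf",
    "occupancy_density",
    "density_overlap",
]


@dataclass
class InteractionSeries:
    """Per-frame geometry of one interaction and its occupancy.

    ``valid`` masks frames with usable geometry; flagged (invalid) frames
    are excluded from the occupancy denominator.
    """

    kind: str
    distance: np.ndarray
    satisfied: np.ndarray
    params: dict
    angle: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.distance), dtype=bool)

    @property
    def occupancy(self) -> float:
        n = int(self.valid.sum())
        if n == 0:
            return 0.0
        return float(self.satisfied[self.valid].sum() / n)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind} " +
                     " ".join(f"{k}={v}" for k, v in sorted(self.params.items())) + "\n")
            fh.write(f"# occupancy={self.occupancy:.6f}\n")
            cols = "frame\tdistance" + ("\tangle" if self.angle is not None else "") + "\tsatisfied\tvalid\n"
            fh.write(cols)
            for f in range(len(self.distance)):
                row = [str(f), f"{self.distance[f]:.4f}"]
                if self.angle is not None:
                    row.append(f"{self.angle[f]:.2f}")
                row += [str(int(self.satisfied[f])), str(int(self.valid[f]))]
                fh.write("\t".join(row) + "\n")


@dataclass
class RDFProfile:
    r: np.ndarray
    g: np.ndarray
    bin_width: float
    counts: np.ndarray
    density: float  # mean target density in the analysis sphere, Å⁻³
    n_reference: int
    n_frames: int


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D grid: origin (Å), isotropic spacing (Å), dims (nx, ny, nz)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0 or any(d < 1 for d in self.dims):
            raise ValueError("invalid grid spec")


@dataclass
class DensityGrid:
    spec: GridSpec
    values: np.ndarray  # per-voxel occupancy fraction in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.spec.dims):
            raise ValueError("values shape does not match grid dims")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("voxel occupancies must lie in [0, 1]")

    def write_dx(self, path) -> None:
        """OpenDX scalar grid, readable by PyMOL/VMD/Chimera."""
        nx, ny, nz = self.spec.dims
        ox, oy, oz = self.spec.origin
        h = self.spec.spacing
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
            fh.write(f"delta {h:.6f} 0 0\ndelta 0 {h:.6f} 0\ndelta 0 0 {h:.6f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(f"object 3 class array type double rank 0 items {nx*ny*nz} data follows\n")
            flat = self.values.ravel()
            for start in range(0, flat.size, 3):
                fh.write(" ".join(f"{v:.6e}" for v in flat[start:start + 3]) + "\n")
            fh.write("object \"density\" class field\n")


# ---------------------------------------------------------------------------
# pairwise interaction series
# ---------------------------------------------------------------------------

def _indices(traj: Trajectory, sel) -> np.ndarray:
    if isinstance(sel, Selection):
        return sel.indices(traj.topology)
    idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    return idx


def _best_fit_normal(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit normal of the best-fit plane and the planarity residual (Å)."""
    centred = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    rms_thickness = s[-1] / np.sqrt(points.shape[0])
    return vt[-1], float(rms_thickness)


def pi_stack_series(traj: Trajectory, ring_a, ring_b,
                    d_max: float = 5.5, theta_max: float = 30.0,
                    planarity_max: float = 0.6) -> InteractionSeries:
    """π-stacking geometry: ring-centroid distance and inter-plane angle.

    Stacked means centroid distance ≤ ``d_max`` *and* the acute angle
    between the ring planes ≤ ``theta_max`` (face-to-face; T-shaped
    arrangements are excluded by default).  Frames where either ring is
    too far from planar (RMS thickness > ``planarity_max`` Å) are flagged
    invalid and dropped from the occupancy denominator.
    """
    ia, ib = _indices(traj, ring_a), _indices(traj, ring_b)
    if ia.size < 5 or ib.size < 5:
        raise ValueError("each ring selection needs at least 5 atoms")
    f = traj.n_frames
    dist = np.empty(f)
    ang = np.empty(f)
    valid = np.ones(f, dtype=bool)
    for k in range(f):
        pa, pb = traj.coords[k][ia], traj.coords[k][ib]
        dist[k] = np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0))
        na, ra = _best_fit_normal(pa)
        nb, rb = _best_fit_normal(pb)
        if ra > planarity_max or rb > planarity_max:
            valid[k] = False
            ang[k] = np.nan
            continue
        cosang = np.clip(abs(np.dot(na, nb)), 0.0, 1.0)
        ang[k] = np.degrees(np.arccos(cosang))  # acute inter-plane angle
    satisfied = valid & (dist <= d_max) & (np.nan_to_num(ang, nan=180.0) <= theta_max)
    return InteractionSeries("pi_stack", dist, satisfied,
                             {"d_max": d_max, "theta_max": theta_max,
                              "planarity_max": planarity_max},
                             angle=ang, valid=valid)


def salt_bridge_series(traj: Trajectory, anionic, cationic, d_max: float = 4.0) -> InteractionSeries:
    """Minimum heavy-atom cross distance between two charged groups."""
    ia, ib = _indices(traj, anionic), _indices(traj, cationic)
    diffs = traj.coords[:, ia, None, :] - traj.coords[:, None, ib, :]
    dist = np.linalg.norm(diffs, axis=-1).reshape(traj.n_frames, -1).min(axis=1)
    return InteractionSeries("salt_bridge", dist, dist <= d_max, {"d_max": d_max})


def hbond_series(traj: Trajectory, donor, hydrogen, acceptor,
                 d_max: float = 3.5, angle_min: float = 135.0) -> InteractionSeries:
    """Single D–H···A hydrogen bond: D···A distance and D–H···A angle.

    ``donor``/``hydrogen``/``acceptor`` each resolve to exactly one atom.
    Bonded means D···A ≤ ``d_max`` and the angle at H ≥ ``angle_min``.
    A missing hydrogen selection raises with a hint that a heavy-atom-only
    criterion (distance cutoff alone) can be emulated with
    ``angle_min=0``.
    """
    if hydrogen is None:
        raise ValueError(
            "hydrogen atom required for the D-H...A angle; for heavy-atom-only "
            "data pass the donor itself as hydrogen and set angle_min=0"
        )
    idx = []
    for name, sel in (("donor", donor), ("hydrogen", hydrogen), ("acceptor", acceptor)):
        i = _indices(traj, sel)
        if i.size != 1:
            raise ValueError(f"{name} selection must resolve to exactly 1 atom, got {i.size}")
        idx.append(int(i[0]))
    d, h, a = idx
    vd = traj.coords[:, d]
    vh = traj.coords[:, h]
    va = traj.coords[:, a]
    dist = np.linalg.norm(vd - va, axis=-1)
    u1 = vd - vh
    u2 = va - vh
    cosang = np.einsum("fi,fi->f", u1, u2)
    norms = np.linalg.norm(u1, axis=-1) * np.linalg.norm(u2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ang = np.degrees(np.arccos(np.clip(cosang / np.where(norms == 0, 1.0, norms), -1.0, 1.0)))
    ang = np.where(norms == 0, 180.0, ang)  # degenerate D==H: treat as linear
    satisfied = (dist <= d_max) & (ang >= angle_min)
    return InteractionSeries("hbond", dist, satisfied,
                             {"d_max": d_max, "angle_min": angle_min}, angle=ang)


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------

def rdf(traj: Trajectory, reference, target, r_max: float, bin_width: float) -> RDFProfile:
    """g(r) of target atoms around reference atoms.

    Distances are histogrammed and normalised by the spherical-shell
    volume and by the mean target density inside the analysis sphere of
    radius ``r_max`` around each reference atom, so an ideal homogeneous
    gas gives g(r) = 1 at every r.
    """
    if not r_max > bin_width > 0:
        raise ValueError("need r_max > bin_width > 0")
    ir, it = _indices(traj, reference), _indices(traj, target)
    if np.intersect1d(ir, it).size:
        raise ValueError("reference and target selections overlap")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(edges.size - 1)
    inside_total = 0
    for k in range(traj.n_frames):
        diffs = traj.coords[k][ir, None, :] - traj.coords[k][None, it, :]
        d = np.linalg.norm(diffs, axis=-1).ravel()
        counts += np.histogram(d, bins=edges)[0]
        inside_total += int((d <= r_max).sum())
    n_obs = traj.n_frames * ir.size
    sphere_vol = 4.0 / 3.0 * np.pi * r_max**3
    density = inside_total / n_obs / sphere_vol
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = counts / n_obs / (shell_vol * density) if density > 0 else np.zeros_like(counts)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFProfile(r=centers, g=g, bin_width=bin_width, counts=counts,
                      density=float(density), n_reference=int(ir.size),
                      n_frames=traj.n_frames)


# ---------------------------------------------------------------------------
# occupancy densities
# ---------------------------------------------------------------------------

def occupancy_density(traj: Trajectory, sel, spec: GridSpec) -> DensityGrid:
    """Fraction of frames with at least one selected atom in each voxel.

    The trajectory should already be superposed on the pocket of interest;
    atoms falling outside the grid raise, because a silently clipped grid
    would bias the overlap statistic.
    """
    idx = _indices(traj, sel)
    origin = np.asarray(spec.origin, dtype=float)
    dims = np.asarray(spec.dims, dtype=int)
    hits = np.zeros(tuple(dims), dtype=np.int64)
    for k in range(traj.n_frames):
        vox = np.floor((traj.coords[k][idx] - origin) / spec.spacing).astype(int)
        if np.any(vox < 0) or np.any(vox >= dims):
            raise ValueError(
                f"frame {k}: selected atoms fall outside the grid; enlarge it"
            )
        uniq = np.unique(vox, axis=0)
        hits[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return DensityGrid(spec, hits / traj.n_frames)


def density_overlap(a: DensityGrid, b: DensityGrid) -> float:
    """Jaccard-like overlap Σ min / Σ max of two congruent occupancy grids.

    1 for identical grids, 0 for disjoint ones; two empty grids are
    considered identical (overlap 1).
    """
    if a.spec != b.spec:
        raise ValueError("grids are not congruent")
    mx = np.maximum(a.values, b.values).sum()
    if mx == 0:
        return 1.0
    return float(np.minimum(a.values, b.values).sum() / mx)
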