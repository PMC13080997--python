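"""Synthetic trajectories with analytically known statistics.

Two generators stand in for equilibrium MD sampling:

* a harmonic (Gaussian) network — Cα positions fluctuate around a fixed
  reference with a user-specified displacement covariance, so the exact
  correlation matrix and (in the collinear limit) the exact
  distance-fluctuation matrix are available in closed form;
* a two-state flexible loop on a near-rigid scaffold — frames alternate
  between two loop conformations with stated populations plus isotropic
  within-state noise, mimicking a docked/undocked loop and providing
  ground-truth labels for clustering-recovery tests.

Frames are i.i.d. draws by default: the downstream observables (distance
fluctuations, displacement correlations, shortest-path maps, cluster
populations) are functionals of the marginal coordinate distribution only,
so temporal correlation would change error bars but not expectations.  An
optional AR(1) mixing coefficient is available for realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import Selection, Structure, Trajectory, rmsd

__all__ = [
    "HarmonicNetworkSpec",
    "TwoStateLoopSpec",
    "make_harmonic_trajectory",
    "ground_truth_correlation",
    "make_two_state_trajectory",
    "collinear_df_closed_form",
    "ideal_helix_backbone",
    "ca_chain_structure",
    "two_state_loop_spec",
]


# ---------------------------------------------------------------------------
# topology builders
# ---------------------------------------------------------------------------

def ca_chain_structure(reference: np.ndarray, first_resid: int = 1) -> Structure:
    """A Cα-only chain over the given reference coordinates."""
    reference = np.asarray(reference, dtype=float)
    n = reference.shape[0]
    return Structure(
        names=np.array(["CA"] * n, dtype=object),
        resids=np.arange(first_resid, first_resid + n),
        resnames=np.array(["ALA"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        coords=reference,
    )


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of the atom bonded to ``c``."""
    angle = np.deg2rad(angle)
    dihedral = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(angle),
                         np.cos(dihedral) * np.sin(angle),
                         np.sin(dihedral) * np.sin(angle)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def ideal_helix_backbone(n_res: int, phi: float = -57.0, psi: float = -47.0,
                         first_resid: int = 1) -> Structure:
    """Backbone (N, CA, C, O) of an ideal α-helix built from internal coordinates.

    Standard bond lengths/angles with uniform (φ, ψ) and ω = 180°; the
    default dihedrals give a canonical right-handed α-helix that a
    secondary-structure assigner classifies as helical away from the
    termini.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    b_n_ca, b_ca_c, b_c_n, b_c_o = 1.458, 1.525, 1.329, 1.231
    a_n_ca_c, a_ca_c_n, a_c_n_ca, a_ca_c_o = 111.2, 116.2, 121.7, 120.8
    omega = 180.0

    N = np.array([0.0, 0.0, 0.0])
    CA = N + np.array([b_n_ca, 0.0, 0.0])
    ang = np.deg2rad(a_n_ca_c)
    C = CA + b_ca_c * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    frames = []
    prev = (N, CA, C)
    for i in range(n_res):
        if i > 0:
            N = _place_atom(*prev, b_c_n, a_ca_c_n, psi)
            CA = _place_atom(prev[1], prev[2], N, b_n_ca, a_c_n_ca, omega)
            C = _place_atom(prev[2], N, CA, b_ca_c, a_n_ca_c, phi)
        O = _place_atom(N, CA, C, b_c_o, a_ca_c_o, psi + 180.0)
        frames.append((N, CA, C, O))
        prev = (N, CA, C)

    coords = np.array(frames).reshape(-1, 3)
    n_atoms = 4 * n_res
    return Structure(
        names=np.array(["N", "CA", "C", "O"] * n_res, dtype=object),
        resids=np.repeat(np.arange(first_resid, first_resid + n_res), 4),
        resnames=np.array(["ALA"] * n_atoms, dtype=object),
        chain_ids=np.array(["A"] * n_atoms, dtype=object),
        coords=coords,
    )


# ---------------------------------------------------------------------------
# harmonic network generator
# ---------------------------------------------------------------------------

@dataclass
class HarmonicNetworkSpec:
    """Gaussian fluctuations of N Cα sites around a reference.

    ``covariance`` is either per-residue 3×3 blocks ``(N, 3, 3)`` (residues
    then mutually independent) or a full ``(3N, 3N)`` displacement
    covariance, in Å².  Positive semi-definiteness is validated.
    """

    reference: np.ndarray
    covariance: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.ndim != 2 or self.reference.shape[1] != 3:
            raise ValueError("reference must have shape (N, 3)")
        if not np.all(np.isfinite(self.reference)):
            raise ValueError("reference must be finite")
        n = self.n_residues
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape == (n, 3, 3):
            self._full = False
        elif cov.shape == (3 * n, 3 * n):
            self._full = True
        else:
            raise ValueError(f"covariance shape {cov.shape} not (N,3,3) or (3N,3N)")
        mats = [cov] if self._full else list(cov)
        for m in mats:
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError("covariance must be symmetric")
            w = np.linalg.eigvalsh(m)
            if w.min() < -1e-8 * max(1.0, abs(w.max())):
                raise ValueError("covariance is not positive semi-definite")
        self.covariance = cov

    @property
    def n_residues(self) -> int:
        return self.reference.shape[0]

    @classmethod
    def isotropic(cls, reference: np.ndarray, sigma, seed: int = 0) -> "HarmonicNetworkSpec":
        """Independent isotropic fluctuations, per-residue σ in Å."""
        reference = np.asarray(reference, dtype=float)
        n = reference.shape[0]
        sig = np.broadcast_to(np.asarray(sigma, dtype=float), (n,))
        cov = np.einsum("i,jk->ijk", sig**2, np.eye(3))
        return cls(reference, cov, seed)

    def full_covariance(self) -> np.ndarray:
        if self._full:
            return self.covariance
        n = self.n_residues
        full = np.zeros((3 * n, 3 * n))
        for i in range(n):
            full[3 * i:3 * i + 3, 3 * i:3 * i + 3] = self.covariance[i]
        return full


def _sqrt_psd(cov: np.ndarray) -> np.ndarray:
    """Symmetric square root; tolerant of semi-definite inputs."""
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def make_harmonic_trajectory(spec: HarmonicNetworkSpec, n_frames: int,
                             ar1: float = 0.0, n_replicas: int = 1) -> Trajectory:
    """Sample frames ``reference + Gaussian displacement``.

    With ``n_replicas > 1`` the frames are split into equal blocks, each
    drawn with a per-replica offset of the seed (mirroring independent MD
    replicas started from different random velocities) and recorded in
    ``replica_bounds``.  ``ar1`` ∈ [0, 1) adds stationary AR(1) memory with
    the same marginal covariance.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0.0 <= ar1 < 1.0:
        raise ValueError("ar1 must be in [0, 1)")
    if n_replicas < 1 or n_frames % n_replicas:
        raise ValueError("n_frames must divide evenly into n_replicas")
    n = spec.n_residues
    root = _sqrt_psd(spec.full_covariance())
    per = n_frames // n_replicas
    blocks, bounds, total = [], [], 0
    for r in range(n_replicas):
        rng = np.random.default_rng([int(spec.seed), r])
        z = rng.standard_normal((per, 3 * n))
        if ar1 > 0.0:
            out = np.empty_like(z)
            out[0] = z[0]
            scale = np.sqrt(1.0 - ar1**2)
            for t in range(1, per):
                out[t] = ar1 * out[t - 1] + scale * z[t]
            z = out
        disp = z @ root.T
        blocks.append(spec.reference[None] + disp.reshape(per, n, 3))
        bounds.append(total)
        total += per
    topo = ca_chain_structure(spec.reference)
    return Trajectory(topo, np.concatenate(blocks, axis=0), tuple(bounds))


def ground_truth_correlation(spec: HarmonicNetworkSpec):
    """Exact displacement correlation implied by the covariance.

    For zero-mean Gaussian displacements the expected dot product
    ⟨Δr_i · Δr_j⟩ is the trace of the (i, j) 3×3 covariance block, so the
    normalised correlation is ``tr Σ_ij / sqrt(tr Σ_ii · tr Σ_jj)`` —
    no sampling involved.
    """
    from .spm import CorrelationMatrix

    n = spec.n_residues
    full = spec.full_covariance()
    tr = np.einsum("ikjk->ij", full.reshape(n, 3, n, 3))
    diag = np.diag(tr).copy()
    zero = diag <= 0.0
    denom = np.sqrt(np.outer(np.where(zero, 1.0, diag), np.where(zero, 1.0, diag)))
    values = tr / denom
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(values=values, resids=np.arange(1, n + 1),
                             zero_variance=np.flatnonzero(zero))


# ---------------------------------------------------------------------------
# two-state loop generator
# ---------------------------------------------------------------------------

@dataclass
class TwoStateLoopSpec:
    """A flexible segment alternating between two conformations A and B.

    The scaffold (all atoms outside ``loop_sel``) sits near-rigidly at the
    topology coordinates with isotropic noise ``scaffold_sigma``; the loop
    atoms take conformation A or B (chosen per frame with probability
    ``p_a`` / ``1 − p_a``) plus isotropic noise ``sigma``.  All σ in Å.
    """

    scaffold: Structure
    loop_sel: Selection
    conf_a: np.ndarray
    conf_b: np.ndarray
    p_a: float = 0.6
    sigma: float = 0.5
    scaffold_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.conf_a = np.asarray(self.conf_a, dtype=float)
        self.conf_b = np.asarray(self.conf_b, dtype=float)
        idx = self.loop_sel.indices(self.scaffold)
        if self.conf_a.shape != (idx.size, 3) or self.conf_b.shape != (idx.size, 3):
            raise ValueError("loop conformations must match the loop selection atom count")
        if not 0.0 <= self.p_a <= 1.0:
            raise ValueError("p_a must be in [0, 1]")
        if self.sigma < 0 or self.scaffold_sigma < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def loop_indices(self) -> np.ndarray:
        return self.loop_sel.indices(self.scaffold)

    def state_separation(self) -> float:
        """Unfitted RMSD between the two loop conformations, Å."""
        return rmsd(self.conf_a, self.conf_b)


def make_two_state_trajectory(spec: TwoStateLoopSpec, n_frames: int):
    """Sample frames and return ``(trajectory, labels, metadata)``.

    ``labels[f]`` is 0 for state A and 1 for state B.  ``metadata`` flags
    ``states_overlap`` when the within-state noise exceeds half the A–B
    RMSD, i.e. when recovery of the states from geometry alone is not
    guaranteed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(int(spec.seed))
    idx = spec.loop_indices
    labels = (rng.random(n_frames) >= spec.p_a).astype(int)  # 0 = A, 1 = B
    coords = np.repeat(spec.scaffold.coords[None], n_frames, axis=0)
    coords += rng.normal(0.0, spec.scaffold_sigma, size=coords.shape) if spec.scaffold_sigma > 0 else 0.0
    confs = np.stack([spec.conf_a, spec.conf_b])
    coords[:, idx] = confs[labels]
    if spec.sigma > 0:
        coords[:, idx] += rng.normal(0.0, spec.sigma, size=(n_frames, idx.size, 3))
    sep = spec.state_separation()
    meta = {
        "p_a": spec.p_a,
        "sigma": spec.sigma,
        "state_separation": sep,
        "states_overlap": bool(spec.sigma > 0.5 * sep),
    }
    return Trajectory(spec.scaffold, coords), labels, meta


def two_state_loop_spec(p_a: float = 0.60, sigma: float = 0.5,
                        separation: float = 8.0, seed: int = 0,
                        first_resid: int = 101, n_res: int = 60,
                        loop: tuple[int, int] = (117, 134),
                        retained: tuple[int, int] = (111, 140)) -> TwoStateLoopSpec:
    """A kinesin-like docked/undocked loop scenario on a helical scaffold.

    The scaffold is an ideal-helix backbone spanning residues
    ``first_resid``..``first_resid+n_res-1``; the loop residues are rigidly
    displaced perpendicular to the helix axis in state B, scaled so that
    the A–B RMSD measured over the *retained* backbone window (the part a
    clustering protocol keeps, anchor residues included) equals
    ``separation``.
    """
    scaffold = ideal_helix_backbone(n_res, first_resid=first_resid)
    loop_sel = Selection.backbone([loop])
    retained_sel = Selection.backbone([retained])
    idx_loop = loop_sel.indices(scaffold)
    idx_ret = retained_sel.indices(scaffold)
    moved = np.isin(idx_ret, idx_loop)
    # |shift| over the moved atoms dilutes into the retained-window RMSD
    shift_mag = separation * np.sqrt(idx_ret.size / moved.sum())
    axis = scaffold.coords[-1] - scaffold.coords[0]
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    conf_a = scaffold.coords[idx_loop]
    conf_b = conf_a + shift_mag * perp
    return TwoStateLoopSpec(scaffold, loop_sel, conf_a, conf_b,
                            p_a=p_a, sigma=sigma, seed=seed)


# ---------------------------------------------------------------------------
# closed-form distance fluctuations (collinear limit)
# ---------------------------------------------------------------------------

def collinear_df_closed_form(positions_1d: np.ndarray, variances: np.ndarray,
                             covariances: np.ndarray | None = None):
    """Exact distance-fluctuation matrix for collinear Gaussian sites.

    For residues on a line whose fluctuations never reorder them, the
    inter-residue distance is |x_j − x_i| = x_j − x_i, so its variance is
    exactly ``σ_i² + σ_j² − 2 cov_ij``.  A guard rejects configurations
    where the minimum gap is not at least 6× the largest σ, outside which
    the ordering assumption (and hence the closed form) may fail.
    """
    from .distance_fluctuation import DFMatrix

    x = np.asarray(positions_1d, dtype=float)
    var = np.asarray(variances, dtype=float)
    n = x.size
    if var.shape != (n,):
        raise ValueError("variances must match positions")
    cov = np.zeros((n, n)) if covariances is None else np.asarray(covariances, dtype=float)
    if cov.shape != (n, n):
        raise ValueError("covariances must be an N×N matrix")
    order = np.argsort(x)
    gaps = np.diff(x[order])
    max_sigma = float(np.sqrt(var.max())) if var.max() > 0 else 0.0
    if n > 1 and max_sigma > 0 and gaps.min() <= 6.0 * max_sigma:
        raise ValueError(
            f"minimum gap {gaps.min():.3g} Å is not > 6×max σ ({max_sigma:.3g} Å); "
            "ordering may be violated and the collinear closed form invalid"
        )
    np.fill_diagonal(cov, var)
    scores = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(scores, 0.0)
    return DFMatrix(scores=scores, resids=np.arange(1, n + 1),
                    meta={"source": "collinear closed form"})
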