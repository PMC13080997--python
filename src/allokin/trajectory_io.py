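"""Structures, trajectories and atom selections.

Thin containers over numpy arrays plus readers/writers backed by
MDAnalysis.  Coordinates are always in ångström, residue numbers are the
1-based author/Uniprot numbering of the input file, and selections are
inclusive residue ranges — the conventions used throughout the motor-domain
literature this package serves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Structure",
    "Trajectory",
    "Selection",
    "load_structure",
    "load_trajectory",
    "write_structure",
    "write_trajectory",
    "reduce",
    "superpose",
    "rmsd",
    "average_structure",
    "kabsch_transform",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: frame-to-frame Cα displacement above which a trajectory is assumed to be
#: broken across periodic boundaries (trajectories must arrive pre-imaged)
MAX_FRAME_JUMP = 20.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """A set of labelled atoms with one coordinate frame.

    Parameters
    ----------
    names, elements, resids, resnames, chain_ids
        Per-atom annotation arrays, all of length ``n_atoms``.  ``resids``
        are the 1-based residue sequence numbers of the source file.
    coords
        ``(n_atoms, 3)`` float array, Å.
    is_hetero, is_water
        Flags for HETATM records and water residues; both retained on load
        but excluded from residue-range selections only if the caller says
        so (waters are ordinary atoms here).
    icodes
        PDB insertion codes; insertion-coded residues are excluded from
        residue-range selections because their sequence position is
        ambiguous.
    """

    names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    elements: np.ndarray | None = None
    is_hetero: np.ndarray | None = None
    is_water: np.ndarray | None = None
    icodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = self.coords.shape[0]
        for attr in ("names", "resids", "resnames", "chain_ids"):
            arr = np.asarray(getattr(self, attr))
            if arr.shape[0] != n:
                raise ValueError(f"{attr} has length {arr.shape[0]}, expected {n}")
            setattr(self, attr, arr)
        self.resids = self.resids.astype(int)
        if self.elements is None:
            self.elements = np.array([_guess_element(nm) for nm in self.names])
        if self.is_hetero is None:
            self.is_hetero = np.zeros(n, dtype=bool)
        if self.is_water is None:
            self.is_water = np.isin(self.resnames, ("HOH", "WAT", "TIP3", "SOL"))
        if self.icodes is None:
            self.icodes = np.full(n, "", dtype=object)
        _check_residue_order(self)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_table(self) -> list[tuple[int, str, str]]:
        """Ordered unique ``(resid, resname, chain_id)`` triples."""
        out, seen = [], set()
        for rid, rn, ch in zip(self.resids, self.resnames, self.chain_ids):
            key = (int(rid), str(ch))
            if key not in seen:
                seen.add(key)
                out.append((int(rid), str(rn), str(ch)))
        return out

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            names=self.names[idx],
            resids=self.resids[idx],
            resnames=self.resnames[idx],
            chain_ids=self.chain_ids[idx],
            coords=self.coords[idx],
            elements=self.elements[idx],
            is_hetero=self.is_hetero[idx],
            is_water=self.is_water[idx],
            icodes=self.icodes[idx],
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))


def _guess_element(name: str) -> str:
    stripped = str(name).strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _check_residue_order(s: Structure) -> None:
    """Residue numbering must be non-decreasing within each chain."""
    for ch in np.unique(s.chain_ids):
        rid = s.resids[s.chain_ids == ch]
        if rid.size and np.any(np.diff(rid) < 0):
            raise ValueError(f"residue numbering not increasing within chain {ch!r}")


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed topology.

    ``replica_bounds`` marks the first frame of each independent replica in
    a concatenated metatrajectory; a single-replica trajectory has
    ``(0,)``.
    """

    topology: Structure
    coords: np.ndarray  # (F, n_atoms, 3), Å
    replica_bounds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (F, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory coordinates must be finite")
        rb = tuple(int(b) for b in self.replica_bounds)
        if not rb or rb[0] != 0 or list(rb) != sorted(set(rb)) or rb[-1] >= self.n_frames:
            raise ValueError(f"invalid replica_bounds {rb} for {self.n_frames} frames")
        self.replica_bounds = rb

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def replica_slices(self) -> list[slice]:
        bounds = list(self.replica_bounds) + [self.n_frames]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(self.topology, coords, self.replica_bounds)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_NAMED_ATOM_SETS = {
    "ca": ("CA",),
    "backbone": BACKBONE_ATOMS,
    "all": None,
}


@dataclass(frozen=True)
class Selection:
    """Residue ranges (1-based, inclusive) plus an atom-name filter.

    ``residues=None`` selects every residue, ``atoms=None`` every atom
    name.  String form: ``"ca:116-134"``, ``"backbone:111-116,135-140"``,
    ``"all"``, or bare ranges such as ``"105-112"``.
    """

    residues: tuple[tuple[int, int], ...] | None = None
    atoms: tuple[str, ...] | None = None

    # -- constructors -------------------------------------------------
    @classmethod
    def parse(cls, spec: str) -> "Selection":
        spec = spec.strip()
        atoms: tuple[str, ...] | None = None
        if ":" in spec:
            head, spec = spec.split(":", 1)
            key = head.strip().lower()
            if key in _NAMED_ATOM_SETS:
                atoms = _NAMED_ATOM_SETS[key]
            else:
                atoms = tuple(a.strip().upper() for a in head.split(",") if a.strip())
        elif spec.lower() in _NAMED_ATOM_SETS:
            return cls(residues=None, atoms=_NAMED_ATOM_SETS[spec.lower()])
        residues = None if spec.lower() in ("", "all") else _parse_ranges(spec)
        return cls(residues=residues, atoms=atoms)

    @classmethod
    def ca(cls, ranges: str | Sequence[tuple[int, int]] | None = None) -> "Selection":
        return cls(residues=_coerce_ranges(ranges), atoms=("CA",))

    @classmethod
    def backbone(cls, ranges: str | Sequence[tuple[int, int]] | None = None) -> "Selection":
        return cls(residues=_coerce_ranges(ranges), atoms=BACKBONE_ATOMS)

    @classmethod
    def from_resids(cls, resids: Iterable[int], atoms: Sequence[str] | None = None) -> "Selection":
        return cls(residues=_resids_to_ranges(resids), atoms=tuple(atoms) if atoms else None)

    # -- resolution ---------------------------------------------------
    def residue_mask(self, resids: np.ndarray) -> np.ndarray:
        if self.residues is None:
            return np.ones(len(resids), dtype=bool)
        mask = np.zeros(len(resids), dtype=bool)
        for lo, hi in self.residues:
            mask |= (resids >= lo) & (resids <= hi)
        return mask

    def mask(self, structure: Structure) -> np.ndarray:
        m = self.residue_mask(structure.resids)
        if self.atoms is not None:
            m &= np.isin(np.char.upper(structure.names.astype(str)), self.atoms)
        if structure.icodes is not None:
            m &= np.asarray([str(c).strip() == "" for c in structure.icodes])
        return m

    def indices(self, structure: Structure) -> np.ndarray:
        """Sorted, duplicate-free atom indices; error on an empty result."""
        idx = np.flatnonzero(self.mask(structure))
        if idx.size == 0:
            raise ValueError(f"selection {self} matches no atoms in the topology")
        return idx

    def resid_list(self) -> list[int] | None:
        if self.residues is None:
            return None
        out: list[int] = []
        for lo, hi in self.residues:
            out.extend(range(lo, hi + 1))
        return sorted(set(out))

    def __str__(self) -> str:  # for error messages and logs
        atoms = "all" if self.atoms is None else ",".join(self.atoms)
        if self.residues is None:
            res = "all"
        else:
            res = ",".join(f"{lo}-{hi}" if lo != hi else str(lo) for lo, hi in self.residues)
        return f"{atoms}:{res}"


def _parse_ranges(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        m = re.fullmatch(r"(-?\d+)\s*-\s*(-?\d+)", part) or re.fullmatch(r"(-?\d+)", part)
        if m is None:
            raise ValueError(f"cannot parse residue range {part!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.lastindex == 2 else lo
        if hi < lo:
            raise ValueError(f"descending residue range {part!r}")
        out.append((lo, hi))
    if not out:
        raise ValueError(f"empty residue range spec {text!r}")
    return tuple(out)


def _coerce_ranges(ranges) -> tuple[tuple[int, int], ...] | None:
    if ranges is None:
        return None
    if isinstance(ranges, str):
        return _parse_ranges(ranges)
    return tuple((int(lo), int(hi)) for lo, hi in ranges)


def _resids_to_ranges(resids: Iterable[int]) -> tuple[tuple[int, int], ...]:
    rs = sorted(set(int(r) for r in resids))
    if not rs:
        raise ValueError("empty residue list")
    ranges, lo, prev = [], rs[0], rs[0]
    for r in rs[1:]:
        if r != prev + 1:
            ranges.append((lo, prev))
            lo = r
        prev = r
    ranges.append((lo, prev))
    return tuple(ranges)


# ---------------------------------------------------------------------------
# file I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _import_mda():
    import MDAnalysis as mda  # deferred: heavy import

    return mda


def load_structure(path, model: int = 1, chain: str | None = None) -> Structure:
    """Read one model (1-based) and optionally one chain from a PDB file.

    Alternate locations are resolved to the highest-occupancy copy;
    heteroatoms and waters are retained but flagged.
    """
    mda = _import_mda()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    u = mda.Universe(str(path))
    n_models = len(u.trajectory)
    if not 1 <= model <= n_models:
        raise ValueError(f"model {model} not in file {path.name} (models 1..{n_models})")
    u.trajectory[model - 1]

    atoms = u.atoms
    chain_ids = _chain_ids(atoms)
    if chain is not None:
        available = sorted(set(chain_ids))
        if chain not in available:
            raise ValueError(
                f"chain {chain!r} not found in {path.name}; available chains: {available}"
            )
        keep = chain_ids == chain
        atoms = atoms[keep]
        chain_ids = chain_ids[keep]

    idx = _resolve_altlocs(atoms)
    atoms = atoms[idx]
    chain_ids = chain_ids[idx]

    record_types = getattr(atoms, "record_types", np.array(["ATOM"] * len(atoms)))
    icodes = getattr(atoms, "icodes", np.full(len(atoms), "", dtype=object))
    return Structure(
        names=atoms.names.astype(object),
        resids=atoms.resids,
        resnames=atoms.resnames.astype(object),
        chain_ids=np.asarray(chain_ids, dtype=object),
        coords=atoms.positions.astype(float),
        elements=None,
        is_hetero=np.asarray(record_types) == "HETATM",
        icodes=np.asarray(icodes, dtype=object),
    )


def _chain_ids(atoms) -> np.ndarray:
    ids = getattr(atoms, "chainIDs", None)
    if ids is None or all(str(c).strip() == "" for c in ids):
        ids = atoms.segids
    return np.asarray([str(c).strip() or "A" for c in ids], dtype=object)


def _resolve_altlocs(atoms) -> np.ndarray:
    """Indices keeping, per (resid, icode, name), the highest-occupancy altloc."""
    altlocs = getattr(atoms, "altLocs", None)
    if altlocs is None or all(str(a).strip() == "" for a in altlocs):
        return np.arange(len(atoms))
    occ = getattr(atoms, "occupancies", np.ones(len(atoms)))
    icodes = getattr(atoms, "icodes", np.full(len(atoms), ""))
    best: dict[tuple, tuple[float, int]] = {}
    for i, (rid, ic, nm) in enumerate(zip(atoms.resids, icodes, atoms.names)):
        key = (int(rid), str(ic), str(nm))
        if key not in best or occ[i] > best[key][0]:
            best[key] = (float(occ[i]), i)
    return np.array(sorted(i for _, i in best.values()), dtype=int)


def load_trajectory(topology: Structure, paths: Sequence) -> Trajectory:
    """Concatenate coordinate files into a metatrajectory.

    Each file becomes one replica; ``replica_bounds`` records the frame at
    which every file starts, mirroring the pooling of independent MD
    replicas into a single analysis sample.  A continuity check rejects
    frame-to-frame Cα jumps above ``MAX_FRAME_JUMP`` Å (periodic-boundary
    artifacts must be removed upstream).
    """
    mda = _import_mda()
    from MDAnalysis.coordinates.core import get_reader_for

    if not paths:
        raise ValueError("no trajectory files given")
    blocks: list[np.ndarray] = []
    bounds: list[int] = []
    total = 0
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        reader_cls = get_reader_for(str(p))
        try:
            reader = reader_cls(str(p))
        except TypeError:
            reader = reader_cls(str(p), n_atoms=topology.n_atoms)
        with reader:
            if reader.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"trajectory {p.name} has {reader.n_atoms} atoms but the "
                    f"topology has {topology.n_atoms}"
                )
            frames = np.array([ts.positions.copy() for ts in reader], dtype=float)
        bounds.append(total)
        total += len(frames)
        blocks.append(frames)
    traj = Trajectory(topology, np.concatenate(blocks, axis=0), tuple(bounds))
    _check_continuity(traj)
    return traj


def _check_continuity(traj: Trajectory, max_jump: float = MAX_FRAME_JUMP) -> None:
    try:
        idx = Selection.ca().indices(traj.topology)
    except ValueError:
        idx = np.arange(traj.n_atoms)
    for sl in traj.replica_slices():
        block = traj.coords[sl][:, idx]
        if len(block) < 2:
            continue
        jumps = np.linalg.norm(np.diff(block, axis=0), axis=-1)
        if jumps.max() > max_jump:
            f = int(np.unravel_index(jumps.argmax(), jumps.shape)[0]) + sl.start
            raise ValueError(
                f"frame {f}->{f + 1} moves an atom by {jumps.max():.1f} Å "
                f"(> {max_jump} Å); trajectory looks periodic-boundary broken"
            )


def _as_universe(structure: Structure, coords: np.ndarray | None = None):
    """Build an in-memory MDAnalysis Universe mirroring a Structure."""
    mda = _import_mda()
    resids = structure.resids
    # residue index per atom, respecting chain boundaries
    keys = list(zip(resids.tolist(), structure.chain_ids.tolist()))
    uniq: dict[tuple, int] = {}
    resindex = np.empty(len(keys), dtype=int)
    for i, k in enumerate(keys):
        resindex[i] = uniq.setdefault(k, len(uniq))
    n_res = len(uniq)
    res_first = np.full(n_res, -1, dtype=int)
    for i, ri in enumerate(resindex):
        if res_first[ri] < 0:
            res_first[ri] = i

    seg_ids = [k[1] for k in uniq]
    seg_uniq: dict[str, int] = {}
    segindex = np.array([seg_uniq.setdefault(s, len(seg_uniq)) for s in seg_ids])

    u = mda.Universe.empty(
        structure.n_atoms,
        n_residues=n_res,
        n_segments=len(seg_uniq),
        atom_resindex=resindex,
        residue_segindex=segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", structure.names.astype(str))
    u.add_TopologyAttr("elements", structure.elements.astype(str))
    u.add_TopologyAttr("resids", np.array([k[0] for k in uniq], dtype=int))
    u.add_TopologyAttr("resnames", structure.resnames[res_first].astype(str))
    u.add_TopologyAttr("segids", np.array(list(seg_uniq), dtype=object).astype(str))
    u.add_TopologyAttr("chainIDs", structure.chain_ids.astype(str))
    u.add_TopologyAttr("occupancies", np.ones(structure.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(structure.n_atoms))
    u.atoms.positions = (coords if coords is not None else structure.coords).astype(np.float32)
    return u


def write_structure(structure: Structure, path, coords: np.ndarray | None = None) -> None:
    """Write a single frame as PDB."""
    u = _as_universe(structure, coords)
    u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write all frames in the format implied by the file extension."""
    mda = _import_mda()
    u = _as_universe(traj.topology)
    path = str(path)
    kwargs = {"multiframe": True} if path.lower().endswith(".pdb") else {}
    with mda.Writer(path, n_atoms=traj.n_atoms, **kwargs) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coords[f].astype(np.float32)
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# geometry operations
# ---------------------------------------------------------------------------

def reduce(traj: Trajectory, sel: Selection) -> Trajectory:
    """Strip a trajectory to the selected atoms (frame count preserved)."""
    idx = sel.indices(traj.topology)
    return Trajectory(traj.topology.subset(idx), traj.coords[:, idx], traj.replica_bounds)


def kabsch_transform(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(R, mobile_centroid, ref_centroid)`` such that
    ``(x - mobile_centroid) @ R.T + ref_centroid`` minimises the RMSD of the
    fitted point sets.
    """
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape:
        raise ValueError(f"point sets differ in shape: {mobile.shape} vs {ref.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for a rigid superposition")
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.as_matrix(), mc, rc


def superpose(traj: Trajectory, reference: int | np.ndarray, fit_sel: Selection | None = None) -> Trajectory:
    """Rigid-body fit every frame to a reference on the fit selection.

    The transform estimated on ``fit_sel`` is applied to *all* atoms of the
    frame.  ``reference`` is a frame index into ``traj`` or an explicit
    coordinate array congruent with the topology.
    """
    fit_sel = fit_sel or Selection.ca()
    idx = fit_sel.indices(traj.topology)
    if idx.size < 3:
        raise ValueError("fit selection resolves to fewer than 3 atoms")
    ref = traj.coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError(f"reference shape {ref.shape} != (n_atoms, 3)")
    ref_fit = ref[idx]
    rc = ref_fit.mean(axis=0)
    mobile = traj.coords[:, idx]
    mc = mobile.mean(axis=1)  # (F, 3)
    # batched Kabsch: SVD of the per-frame cross-covariance matrices
    h = np.einsum("fni,nj->fij", mobile - mc[:, None], ref_fit - rc)
    u, _, vt = np.linalg.svd(h)
    det = np.sign(np.linalg.det(np.matmul(u, vt)))  # proper rotations only
    signs = np.ones((traj.n_frames, 3))
    signs[:, 2] = det
    rot_t = np.matmul(u * signs[:, None, :], vt)  # = Rᵀ for mobile -> ref
    out = np.einsum("fni,fij->fnj", traj.coords - mc[:, None], rot_t) + rc
    return traj.with_coords(out)


def _pair_atoms(a: Structure, b: Structure, sel: Selection | None) -> tuple[np.ndarray, np.ndarray]:
    """Match atoms across structures by (resid, atom name), chain-agnostic."""
    def keyed(s: Structure, mask: np.ndarray) -> dict[tuple[int, str], int]:
        out: dict[tuple[int, str], int] = {}
        for i in np.flatnonzero(mask):
            key = (int(s.resids[i]), str(s.names[i]).upper())
            if key in out:
                raise ValueError(f"duplicate atom {key} — disambiguate by loading one chain")
            out[key] = i
        return out

    mask_a = sel.mask(a) if sel else np.ones(a.n_atoms, dtype=bool)
    mask_b = sel.mask(b) if sel else np.ones(b.n_atoms, dtype=bool)
    ka, kb = keyed(a, mask_a), keyed(b, mask_b)
    common = sorted(set(ka) & set(kb))
    if not common:
        raise ValueError("no common atoms between the two structures under this selection")
    return (np.array([ka[k] for k in common]), np.array([kb[k] for k in common]))


def rmsd(a, b, sel: Selection | None = None, fit: bool = False) -> float:
    """Root-mean-square deviation in Å between two structures or frames.

    ``Structure`` inputs are paired by residue number + atom name over the
    residues resolved in both; plain arrays must already be congruent.
    With ``fit=True`` the deviation is measured after least-squares
    superposition.
    """
    if isinstance(a, Structure) and isinstance(b, Structure):
        ia, ib = _pair_atoms(a, b, sel)
        xa, xb = a.coords[ia], b.coords[ib]
    else:
        xa = np.asarray(a, dtype=float)
        xb = np.asarray(b, dtype=float)
        if xa.shape != xb.shape:
            raise ValueError(f"coordinate shapes differ: {xa.shape} vs {xb.shape}")
    if fit:
        R, mc, rc = kabsch_transform(xb, xa)
        xb = (xb - mc) @ R.T + rc
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=-1))))


def average_structure(traj: Trajectory, fit_sel: Selection | None = None) -> np.ndarray:
    """Per-atom mean coordinates, optionally after superposing on a selection."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if fit_sel is not None:
        traj = superpose(traj, 0, fit_sel)
    return traj.coords.mean(axis=0)
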