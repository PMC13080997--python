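"""End-to-end comparison of catalytic states from one configuration file.

A run configuration declares a set of labelled states (each a
topology + trajectory files, or a synthetic generator for testing), the
ordered state transitions to difference, named regions, and per-analysis
parameters.  :func:`run` executes DF, SPM and (optionally) the
loop-clustering protocol for every state, ΔDF for every transition, and
writes plain-text artifacts plus a manifest from which the run is fully
reconstructable.  Re-running with the same configuration and seed
reproduces the numeric artifacts byte for byte.

Configuration (YAML)::

    seed: 1
    states:
      - label: ATP
        topology: atp.pdb
        trajectories: [r1.dcd, r2.dcd]
      - label: toy
        synthetic: {kind: harmonic, n_residues: 30, sigma: 0.4, n_frames: 400}
    transitions:
      - {initial: ATP, final: toy}
    profiles: {residues: [127]}
    regions: {L5: "116-134"}
    analyses:
      df: {replica_mode: pooled}
      spm: {cutoff: 6.0, keep_frac: 0.2}
      loop_clustering: {enabled: false, epsilon: 5.0}
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .distance_fluctuation import compute_df, delta_df, residue_profile, write_matrix
from .loop_clustering import ClusteringProtocolConfig, run_protocol
from .spm import (
    average_distance_matrix,
    build_graph,
    correlation_matrix,
    export_spm,
    reference_structure,
    shortest_path_map,
    write_square_matrix,
)
from .synthetic_data import (
    HarmonicNetworkSpec,
    ideal_helix_backbone,
    make_harmonic_trajectory,
    make_two_state_trajectory,
    two_state_loop_spec,
)
from .trajectory_io import Selection, Trajectory, load_structure, load_trajectory, reduce, write_structure

__all__ = ["RunConfig", "PipelineError", "run", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


class RunConfig:
    """Validated run configuration."""

    def __init__(self, data: dict):
        if not isinstance(data, dict):
            raise ValueError("configuration must be a mapping")
        self.seed = int(data.get("seed", 0))
        states = data.get("states")
        if not states:
            raise ValueError("configuration must declare at least one state")
        self.states: list[dict] = []
        labels = set()
        for i, st in enumerate(states):
            if "label" not in st:
                raise ValueError(f"state #{i} has no label")
            label = str(st["label"])
            if label in labels:
                raise ValueError(f"duplicate state label {label!r}")
            labels.add(label)
            if "synthetic" not in st and ("topology" not in st or "trajectories" not in st):
                raise ValueError(
                    f"state {label!r} needs either 'synthetic' or 'topology' + 'trajectories'"
                )
            self.states.append(dict(st))
        self.transitions: list[tuple[str, str]] = []
        for tr in data.get("transitions", []) or []:
            if isinstance(tr, dict):
                ini, fin = tr.get("initial"), tr.get("final")
            else:
                ini, fin = tr  # [initial, final]
            if ini not in labels or fin not in labels:
                raise ValueError(f"transition {ini!r}->{fin!r} references unknown states")
            self.transitions.append((str(ini), str(fin)))
        self.regions = {str(k): Selection.parse(str(v))
                        for k, v in (data.get("regions") or {}).items()}
        self.profiles = [int(r) for r in (data.get("profiles") or {}).get("residues", [])]
        analyses = data.get("analyses") or {}
        self.df_params = dict(analyses.get("df") or {})
        self.spm_params = dict(analyses.get("spm") or {})
        self.cluster_params = dict(analyses.get("loop_clustering") or {})
        self.raw = data

        for key in ("cutoff", "keep_frac"):
            if key in self.spm_params and float(self.spm_params[key]) <= 0 and key == "cutoff":
                raise ValueError("spm cutoff must be positive")
        if "epsilon" in self.cluster_params and float(self.cluster_params["epsilon"]) <= 0:
            raise ValueError("clustering epsilon must be positive")
        mode = self.df_params.get("replica_mode", "pooled")
        if mode not in ("pooled", "per_replica_mean"):
            raise ValueError(f"unknown df replica_mode {mode!r}")


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        return RunConfig(yaml.safe_load(fh))


def _state_seed(global_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(global_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _materialise_state(state: dict, seed: int) -> Trajectory:
    if "synthetic" in state:
        params = dict(state["synthetic"])
        kind = params.pop("kind", "harmonic")
        params.setdefault("seed", seed)
        n_frames = int(params.pop("n_frames", 500))
        if kind == "harmonic":
            n_res = int(params.pop("n_residues", 30))
            sigma = params.pop("sigma", 0.5)
            ar1 = float(params.pop("ar1", 0.0))
            n_replicas = int(params.pop("n_replicas", 1))
            ref = reduce_to_ca_reference(n_res)
            spec = HarmonicNetworkSpec.isotropic(ref, sigma, seed=int(params.pop("seed")))
            return make_harmonic_trajectory(spec, n_frames, ar1=ar1, n_replicas=n_replicas)
        if kind == "twostate":
            spec = two_state_loop_spec(
                p_a=float(params.pop("p_a", 0.60)),
                sigma=float(params.pop("sigma", 0.5)),
                separation=float(params.pop("separation", 8.0)),
                seed=int(params.pop("seed")),
            )
            traj, _, _ = make_two_state_trajectory(spec, n_frames)
            return traj
        raise ValueError(f"unknown synthetic kind {kind!r}")
    topo = load_structure(state["topology"], chain=state.get("chain"))
    return load_trajectory(topo, state["trajectories"])


def reduce_to_ca_reference(n_res: int) -> np.ndarray:
    """Cα positions of an ideal helix — a compact, contact-rich reference."""
    helix = ideal_helix_backbone(n_res)
    idx = Selection.ca().indices(helix)
    return helix.coords[idx]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run(config: RunConfig | dict, outdir, seed: int | None = None, log=print) -> Path:
    """Execute every requested analysis; return the artifact directory.

    On a stage failure the artifacts produced so far are retained and a
    :class:`PipelineError` naming the failing stage is raised.
    """
    if isinstance(config, dict):
        config = RunConfig(config)
    if seed is not None:
        config = RunConfig({**config.raw, "seed": int(seed)})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package": "allokin",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "df": {"replica_mode": config.df_params.get("replica_mode", "pooled"),
                   "ddof": int(config.df_params.get("ddof", 0))},
            "spm": {"cutoff": float(config.spm_params.get("cutoff", 6.0)),
                    "keep_frac": float(config.spm_params.get("keep_frac", 0.2)),
                    "reference_epsilon": float(config.spm_params.get("reference_epsilon", 2.0))},
            "loop_clustering": {"enabled": bool(config.cluster_params.get("enabled", False)),
                                "epsilon": float(config.cluster_params.get("epsilon", 5.0)),
                                "linkage": config.cluster_params.get("linkage", "average")},
        },
        "inputs": {},
        "states": [],
        "outputs": [],
    }

    df_by_state: dict[str, object] = {}
    stage = "setup"
    try:
        for i, state in enumerate(config.states):
            label = state["label"]
            stage = f"state:{label}:load"
            state_seed = _state_seed(config.seed, i)
            traj = _materialise_state(state, state_seed)
            for key in ("topology",):
                if key in state:
                    manifest["inputs"][str(state[key])] = _sha256(state[key])
            for p in state.get("trajectories", []) or []:
                manifest["inputs"][str(p)] = _sha256(p)
            sdir = outdir / f"state_{label}"
            sdir.mkdir(exist_ok=True)
            manifest["states"].append({"label": label, "seed": state_seed,
                                       "n_frames": traj.n_frames,
                                       "n_atoms": traj.n_atoms,
                                       "replica_bounds": list(traj.replica_bounds)})
            log(f"[{label}] {traj.n_frames} frames, {traj.n_atoms} atoms")

            stage = f"state:{label}:df"
            df = compute_df(traj,
                            replica_mode=config.df_params.get("replica_mode", "pooled"),
                            ddof=int(config.df_params.get("ddof", 0)))
            df.meta["state"] = label
            write_matrix(df, sdir / "df.mat")
            df_by_state[label] = df

            stage = f"state:{label}:spm"
            _, ref = reference_structure(
                traj, epsilon=float(config.spm_params.get("reference_epsilon", 2.0)))
            corr = correlation_matrix(traj, ref)
            dist = average_distance_matrix(traj)
            write_square_matrix(corr.values, corr.resids, sdir / "corr.mat", "correlation")
            write_square_matrix(dist.values, dist.resids, sdir / "avgdist.mat", "avgdist")
            graph = build_graph(corr, dist, cutoff=float(config.spm_params.get("cutoff", 6.0)))
            spmap = shortest_path_map(graph, keep_frac=float(config.spm_params.get("keep_frac", 0.2)))
            export_spm(spmap, reduce(traj, Selection.ca()).topology, str(sdir / "spm_"))

            if config.cluster_params.get("enabled", False):
                stage = f"state:{label}:loop_clustering"
                cconf = _cluster_config(config.cluster_params)
                result, reduced_traj = run_protocol(traj, cconf)
                _write_cluster_outputs(result, reduced_traj, sdir)

            manifest["outputs"].extend(
                str(p.relative_to(outdir)) for p in sorted(sdir.iterdir()))

        for ini, fin in config.transitions:
            stage = f"transition:{fin}-minus-{ini}"
            dd = delta_df(df_by_state[fin], df_by_state[ini])
            name = f"ddf_{fin}_minus_{ini}.mat"
            write_matrix(dd, outdir / name)
            manifest["outputs"].append(name)
            for resid in config.profiles:
                if resid not in dd.resids:
                    continue
                prof = residue_profile(dd, resid)
                pname = f"profile_res{resid}_{fin}_minus_{ini}.tsv"
                with open(outdir / pname, "w") as fh:
                    fh.write("residue\tddf\n")
                    for r, v in zip(dd.resids, prof):
                        fh.write(f"{r}\t{v:.17g}\n")
                manifest["outputs"].append(pname)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def _cluster_config(params: dict) -> ClusteringProtocolConfig:
    kwargs = {}
    if "loop" in params:
        kwargs["loop"] = Selection.backbone(str(params["loop"]))
    if "anchor" in params:
        kwargs["anchor"] = Selection.backbone(str(params["anchor"]))
    if "stable_ss" in params:
        kwargs["stable_ss"] = Selection.parse(str(params["stable_ss"]))
    if "epsilon" in params:
        kwargs["epsilon"] = float(params["epsilon"])
    if "linkage" in params:
        kwargs["linkage"] = str(params["linkage"])
    return ClusteringProtocolConfig(**kwargs)


def _write_cluster_outputs(result, reduced_traj, sdir: Path) -> None:
    with open(sdir / "cluster_labels.tsv", "w") as fh:
        fh.write("frame\tcluster\n")
        for f, lab in enumerate(result.labels):
            fh.write(f"{f}\t{lab}\n")
    with open(sdir / "cluster_populations.tsv", "w") as fh:
        fh.write("cluster\tpopulation\tcentroid_frame\n")
        for k, (pop, cf) in enumerate(zip(result.populations, result.centroid_frames)):
            fh.write(f"{k}\t{pop:.6f}\t{cf}\n")
    for k, cf in enumerate(result.centroid_frames):
        write_structure(reduced_traj.topology, sdir / f"centroid_{k}.pdb",
                        coords=reduced_traj.coords[cf])
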