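# allokin

Allosteric analysis of molecular-dynamics trajectories of protein motor
domains: distance-fluctuation matrices, shortest path maps, a
loop-conformation clustering protocol, and noncovalent interaction
metrics — with synthetic trajectory generators that make every stage
testable against exact ground truth.

The package is aimed at structural-bioinformatics work on proteins whose
function is driven by allosteric communication between distant sites — the
motivating system is the kinesin-5 motor domain, whose nucleotide pocket
(P-loop, Switch I/II), drug-binding loop L5 and microtubule interface talk
to each other across catalytic states (ATP-bound, ADP-bound, apo,
inhibitor-bound) — but every analysis applies to any topology + trajectory
pair in standard formats (PDB, DCD, XTC, TRR, Amber NetCDF, multi-model
PDB).

## The statistics it computes

**Distance fluctuation (DF).** For each residue pair *(i, j)* the variance
of the inter-Cα distance over the trajectory,

    DF_ij = ⟨(d_ij − ⟨d_ij⟩)²⟩   [Å²]

Low DF means the pair moves as one rigid unit: it is allosterically
*coordinated*. DF needs no superposition (it only involves internal
distances). **ΔDF** matrices subtract the DF matrix of an initial state
from that of a final state, following the order of the catalytic cycle:
positive entries flag coordination *loss* across the transition, negative
entries a gain.

**Shortest path map (SPM).** Residue displacement correlations with
respect to the most representative structure (the centroid of the largest
RMSD cluster of the Cα-aligned trajectory),

    C_ij = ⟨Δr_i · Δr_j⟩ / √(⟨Δr_i²⟩ ⟨Δr_j²⟩)

define a graph whose nodes are residues; two residues are joined only if
their mean Cα–Cα distance stays below 6 Å, with edge length
`l_ij = −ln |C_ij|`. One shortest path is traced between every residue
pair and each edge is credited for every path that crosses it; the most
travelled edges form the final map — the route along which allosteric
communication concentrates.

**Loop clustering.** A four-step protocol for flexible-loop states: strip
to backbone and align; align on the residues with stable secondary
structure and average; fit each frame to a helix anchor flanking the loop;
then hierarchically cluster the retained loop backbone on pairwise RMSD
with merge cutoff ε (5 Å default). The pairwise RMSD is deliberately
computed without per-pair re-fitting so that a loop that swings away from
its docked position scores as a different state even if its internal shape
is unchanged.

**Interaction metrics.** π-stacking (ring-centroid distance + inter-plane
angle), salt bridges (minimum heavy-atom cross distance), hydrogen bonds
(D···A distance + D–H···A angle), each reported per frame with an
*occupancy*; radial distribution functions; and 3-D occupancy density
grids compared with the overlap score Σ min(a,b)/Σ max(a,b).

## Worked example

Two synthetic states of a 30-residue helix, one tightly coordinated
(σ = 0.3 Å) and one loosely coordinated (σ = 0.6 Å):

```python
import numpy as np
from allokin import (HarmonicNetworkSpec, make_harmonic_trajectory, compute_df,
                     delta_df, correlation_matrix, average_distance_matrix,
                     build_graph, shortest_path_map, path_between)
from allokin.pipeline import reduce_to_ca_reference

ref = reduce_to_ca_reference(30)                        # Cα helix, residues 1-30
tight = HarmonicNetworkSpec.isotropic(ref, 0.3, seed=1)
loose = HarmonicNetworkSpec.isotropic(ref, 0.6, seed=2)
t1 = make_harmonic_trajectory(tight, 2000)
t2 = make_harmonic_trajectory(loose, 2000)

df1, df2 = compute_df(t1), compute_df(t2)
dd = delta_df(df2, df1)                                 # final − initial
print(f"mean DF tight: {df1.scores[np.triu_indices(30,1)].mean():.3f} A^2")
print(f"mean DF loose: {df2.scores[np.triu_indices(30,1)].mean():.3f} A^2")
print(f"mean dDF (loose - tight): {dd.deltas[np.triu_indices(30,1)].mean():.3f} A^2")

corr = correlation_matrix(t1, ref, superpose_frames=False)
dist = average_distance_matrix(t1)
g = build_graph(corr, dist, cutoff=7.0)
spmap = shortest_path_map(g, keep_frac=0.2)
print(f"graph: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
print(f"retained map: {spmap.retained.number_of_edges()} edges "
      f"(max usage {max(spmap.edge_usage.values())} of {spmap.n_paths} paths)")
paths, best = path_between(g, [5], [25])
print(f"best 5->25 path: {' -> '.join(map(str, best.nodes))}  (length {best.length:.2f})")
```

prints

```
mean DF tight: 0.177 A^2
mean DF loose: 0.719 A^2
mean dDF (loose - tight): 0.542 A^2
graph: 30 nodes, 110 edges
retained map: 27 edges (max usage 79 of 435 paths)
best 5->25 path: 5 -> 7 -> 10 -> 14 -> 18 -> 21 -> 25  (length 26.06)
```

The independent-site fluctuations scale DF with σ² (0.719/0.177 ≈ 4 = the
σ ratio squared), the ΔDF of the loose-minus-tight "transition" is
uniformly positive (coordination loss), and the map concentrates traffic
on the helix backbone: with weak correlations everywhere, shortest paths
hop along spatial neighbours between the two endpoints.

The same analyses run from the shell (`allokin info | synth | df | ddf |
df-profile | spm | spm-path | loopcluster | interact | run`); `allokin run
--config study.yaml --out artifacts/` executes a whole multi-state study
(DF + SPM + clustering per state, ΔDF per declared transition) and writes
a manifest that makes the run reproducible bit for bit.

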