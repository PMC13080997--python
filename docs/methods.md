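# Methods

This note documents the models behind each analysis, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions that affect results.

## Distance fluctuations

`compute_df` estimates, for every residue pair, the variance of the
inter-Cα distance across frames. The estimator is the population variance
(divide by F), matching the expectation form of the definition; an
unbiased variant is available through `ddof=1` and changes nothing at the
frame counts MD produces. Distances are internal coordinates, so no
superposition is performed and the statistic is exactly invariant to
per-frame rigid-body motion (verified to 1e-8 Å² in the tests).

Two replica conventions exist for a metatrajectory (several independent
trajectories concatenated, with boundaries recorded):

* `pooled` (default) — one variance over all frames. This treats the
  replicas as one equilibrium sample and includes the between-replica
  component of the variance.
* `per_replica_mean` — the mean of per-replica variances, which discards
  that between-replica component. By the law of total variance pooled ≥
  per-replica-mean, with equality only when all replicas share the same
  mean distances.

Both are implemented because published workflows use both phrasings
interchangeably; which one a figure used is rarely stated. The difference
is a diagnostic in itself: a large gap flags replicas that sample
different basins.

ΔDF is the elementwise difference final-state minus initial-state, taken
along the direction of the catalytic cycle. Positive means the pair's
distance variance grew — a loss of coordination. `region_summary`
aggregates matrix blocks with a mean (default) or median; region-level
statements in the literature never state their aggregation statistic, so
it is a parameter here.

## Shortest path maps

The reference structure for displacement correlations is the centroid of
the most populated cluster after Cα alignment: frames are hierarchically
clustered on pairwise Cα RMSD (merge cutoff 2 Å by default — no published
value exists for this internal step; 2 Å separates visibly distinct
backbone arrangements while tolerating thermal noise) and the member of
the largest cluster minimising summed RMSD to its mates is returned.
Trajectories longer than `max_cluster_frames` (2000) are strided for this
O(F²) step only; the centroid is then selected among the strided frames.
At MD frame counts the centroid of a dominant basin is insensitive to a
10–20× stride, which is why striding is the default rather than a
subsampling option the user must remember.

Correlations are computed against the reference positions, not the mean:
`C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩)` with `Δr` the displacement from
the reference after Cα superposition. For trajectories generated directly
in the reference frame (the synthetic generators), superposition can be
skipped (`superpose_frames=False`); fitting a near-rigid global transform
would otherwise remove six degrees of freedom and bias correlations of
strongly collective modes. Residues with zero displacement variance are
flagged and isolated (degree-0 nodes) rather than raising, so rigid
synthetic scaffolds remain analyzable.

Graph construction joins residues whose *average* Cα–Cα distance is below
6 Å — a deliberately strict contact criterion that keeps only persistent
neighbours — with edge length `−ln |C_ij|`. The natural log is used; the
published formula writes "log" without a base, and path ranking is
base-invariant (a uniform rescaling), so only reported lengths depend on
the choice. Anticorrelated pairs count as coupled (|C|); pairs with
C = 0 get no edge (infinite length).

One shortest path is traced per unordered node pair. Ties between
equal-length paths are broken by the lexicographically smallest node
sequence, written from the lower-numbered endpoint; determinism is
required for a testable edge count, and the exhaustive-enumeration oracle
in the test suite applies the same rule independently. Path-length
comparisons use a relative tolerance of 1e-9 so that floating-point sums
of identical weights tie as they should. Edge usage counts are
accumulated over all paths; node usage is defined as the summed usage of
incident edges (so Σ node usage = 2 Σ edge usage, an identity the tests
assert). The retained map keeps edges whose usage reaches
`keep_frac` × the maximum usage (default 0.2) — the published procedure
calls this threshold arbitrary, and a fraction of the maximum makes the
default scale-free across system sizes.

## Loop clustering

The protocol prepares frames so that *position relative to the scaffold*,
not loop shape alone, distinguishes conformations:

1. strip to backbone (N, CA, C, O), align all frames to frame 0;
2. align on residues stably structured in every input trajectory
   (secondary structure by the DSSP implementation in MDAnalysis,
   hydrogens inferred; a residue is "stable" when helix/strand in ≥ 75%
   of frames — stability is never defined in the protocols this follows,
   so the threshold is a parameter) and average the aligned frames;
3. fit every frame to the helix-anchor subselection (defaults: anchor
   111–116 ∪ 135–140, loop window 111–140, the α2/L5 numbering of human
   kinesin-5) of the averaged structure; retain the loop-window backbone;
4. agglomerative clustering on pairwise no-refit RMSD, merging until the
   closest pair of clusters is further apart than ε = 5 Å.

Average linkage is the default (the protocol's source names only
"hierarchical agglomerative"; average linkage is the common default of
the MD tooling involved and is robust to the elongated clusters noise
produces); single and complete linkage are selectable. Cluster labels are
reported sorted by decreasing population, each with its population
fraction and a centroid — the member frame minimising summed RMSD to its
cluster.

## Interaction metrics

All thresholds are parameters and are recorded in every output header,
because the SI figures these metrics serve never state their criteria.
Defaults are the field's conventional heavy-atom values:

| metric | criterion | defaults |
|---|---|---|
| π-stacking | centroid distance ≤ d_max and acute inter-plane angle ≤ θ_max | 5.5 Å, 30° |
| salt bridge | min heavy-atom cross distance ≤ d_max | 4.0 Å |
| hydrogen bond | D···A ≤ d_max and D–H···A angle ≥ θ_min | 3.5 Å, 135° |

Ring planes come from the SVD best-fit plane; frames whose ring RMS
thickness exceeds 0.6 Å are flagged invalid and excluded from the
occupancy denominator rather than silently counted. The 30° angle cap
excludes T-shaped arrangements by design — the metric targets
face-to-face stacking.

The RDF normalises by shell volume and by the mean target density inside
the analysis sphere of radius r_max around the reference selection, so a
homogeneous gas gives g(r) = 1 without knowledge of any simulation box.
The density-overlap score Σ min/Σ max on per-voxel occupancy fractions is
this package's definition (published comparisons of ligand densities are
typically visual); it is 1 for identical grids, 0 for disjoint ones, and
two all-zero grids count as identical.

## Synthetic generators

The harmonic generator draws i.i.d. Gaussian displacements about a fixed
reference with a user-specified covariance (per-residue 3×3 blocks or a
full 3N×3N matrix). Frames are independent because every downstream
observable here is a functional of the marginal coordinate distribution;
autocorrelation would change convergence rates, not expectations. An
AR(1) mixing coefficient is available for realism and defaults off.
Multi-replica mode splits frames into equal blocks with a per-replica
seed offset, mirroring replicas launched from different random
velocities. Exact expectations are available in closed form: the
correlation matrix from the covariance-block traces, and the DF matrix in
the collinear far-apart limit (DF_ij = σ_i² + σ_j² − 2cov_ij, guarded by
a minimum-gap check of 6× the largest σ so the ordering assumption
holds).

The two-state loop generator puts an ideal-helix backbone scaffold
(internal-coordinate construction with canonical φ = −57°, ψ = −47°)
under small isotropic noise (0.1 Å) and lets a designated loop window
alternate between two conformations with stated populations plus
within-state noise. Defaults emulate the docked/undocked loop scenario
the clustering protocol was designed for: state populations 0.60/0.40, a
rigid displacement scaled so the A–B RMSD over the retained clustering
window is 8 Å, within-state noise σ = 0.5 Å. When σ exceeds half the A–B
separation the generator flags the states as overlapping instead of
erroring. Ground-truth labels are returned for recovery tests.

What the generators do **not** emulate: anharmonicity, correlated
solvent/thermostat artifacts, conformational exchange kinetics,
side-chain chemistry, and periodic-boundary imaging. Passing tests
therefore demonstrate that the estimators recover known marginal
statistics and that the protocol logic is correct — not that any MD force
field or sampling protocol is adequate. Trajectories are assumed
pre-imaged; loading rejects frame-to-frame Cα jumps above 20 Å rather
than attempting engine-specific unwrapping.

## Conventions and degenerate inputs

* Residue numbers are 1-based author/Uniprot numbering; selections are
  inclusive ranges (`116-134` includes both ends). Insertion-coded
  residues are excluded from range selections; alternate locations
  resolve to the highest-occupancy copy.
* Cross-structure RMSD pairs atoms by residue number + atom name over the
  residues resolved in both structures (chain-agnostic; load a single
  chain first when numbering collides).
* Superposition is closed-form least-squares (Kabsch); fits need ≥ 3
  atoms. Matrix files are whitespace-delimited text with 17 significant
  digits, so a write/read round trip is bit-identical.
* DF requires ≥ 2 frames and exactly one atom per residue in the
  selection; correlation requires ≥ 2 frames; clustering requires ≥ 2
  frames and a positive ε.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` size their inputs so
that statistical tolerances are meaningful: closed-form DF and
correlation recovery use 20 000 frames (sampling error well under the 5%
/ 0.05 acceptance bands), rigid-body invariance uses 200 frames of a
100-residue structure, the shortest-path oracle exhausts 20 random graphs
of ≤ 12 nodes (half with tie-rich dyadic weights), two-state recovery
uses 5 000 frames at the default generator conditions plus 20 seeds at
400 frames for label agreement, and the Poisson-gas RDF uses ≥ 10⁵
in-sphere samples with bins wide enough that the 0.05 deviation bound
sits beyond 3σ of shot noise.

## Known limitations

* The SPM counts a single path per pair; co-optimal path ensembles and
  betweenness variants are out of scope.
* Secondary-structure stability depends on the DSSP hydrogen guess when
  explicit hydrogens are absent.
* `reference_structure` strides very long trajectories for its O(F²)
  clustering step; with a pathological multimodal trajectory and an
  aggressive stride the selected centroid can differ from the full-frame
  answer.
* Regions (L5, switches, P-loop) are user-declared selections; nothing is
  inferred from structure.
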