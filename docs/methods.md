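# Methods

`mdcna` implements the correlation-network view of protein dynamics: given a
coordinate ensemble (an MD trajectory or a generated surrogate), it asks
which residues move together, how the collective motion decomposes into a
few dominant modes, and which residues sit on the communication routes
between groups of collectively moving residues.  This note records the
models, conventions and numerical choices behind each stage, and what the
synthetic benchmarks do and do not establish.

## Coordinate handling

Coordinates are Cartesian angstroms throughout.  Residue numbers follow the
source file (author numbering — a kinase fragment numbered 392–659 keeps
those numbers), because every residue-level claim one makes about such a
system (salt-bridge partners, spine members, mutation sites) is stated in
author numbering.  Atom indices are 0-based and internal.  Insertion-coded
residues are rejected rather than silently renumbered; alternate locations
other than "A"/blank are discarded with a warning.  Multi-chain files
require the selection to name a chain; single-chain files default to it.

Two trajectory formats are supported: multi-model PDB, and a plain-text
"xyz-frames" format (per frame: an atom-count line, then one `x y z` line
per atom in fixed order).  xyz-frames coordinates are written with full
`repr` precision, so write-then-read round trips are bit-exact and every
downstream matrix is reproducible to the bit.

## Superposition and monitors

Superposition is the Kabsch SVD fit with reflection correction (determinant
forced to +1).  The fit set must contain at least three non-collinear atoms;
collinearity is detected by a rank test with tolerance 1e-8.  RMSD series
fit each frame on a *fit* selection and measure over a separate *measure*
selection, so that local deviations are expressed relative to a rigid core
(the classic C-lobe-fit protocol).  The reference is the first frame unless
a reference structure (e.g. an energy-minimised model) is supplied.

"Backbone" in a selection context means N, CA, C, O.  Side-chain distance
monitors default to the minimum over side-chain heavy-atom pairs; a config
override can pin specific atoms (the two conventions bracket what published
distance plots may have used, since figure captions rarely name atoms).  No
iterative mean-structure superposition and no mass weighting are applied.

## Essential dynamics (Cα PCA)

Frames are superposed to the ensemble mean (one fit→mean iteration,
all-Cα fit by default; the fit selection is configurable).  The analysed
covariance is the population (1/F) covariance of the 3N fitted coordinates.
Eigenpairs come from the SVD of the centred coordinate matrix — numerically
equivalent to diagonalising the 3N×3N covariance, stable when F < 3N, and
cross-checked in the tests against a dense eigensolver on the explicit
covariance.  At most min(3N, F−1) modes are retained.  Signs follow a fixed
convention (largest-magnitude component positive) so output does not depend
on the eigensolver or BLAS build.  Variance fractions are reported to two
decimals in the tables.

Subspace similarity uses the root mean-square inner product over the first
D = 10 modes,

    RMSIP = sqrt( (1/D) Σ_i Σ_j (a_i · b_j)² ),

which is 1 for identical and 0 for orthogonal subspaces and is invariant to
any orthonormal remixing within each subspace.  A caveat the synthetic
benchmark makes explicit: RMSIP between independent draws is only
informative when the leading D eigenvalues are well separated.  If the D-th
mode cuts through a degenerate multiplet (as happens with equal-sized
blocks and isotropic noise, where each block contributes a threefold-
degenerate eigenvalue), the empirical eigenvectors inside the multiplet are
arbitrary and the overlap drops for reasons that have nothing to do with
the method.  The replicate-overlap benchmark therefore uses unequal block
sizes and anisotropic per-axis sigma (1.0, 0.7, 0.5 Å) to spread the
leading spectrum.

## Dynamic cross-correlation

The DCCM element is

    C_ij = ⟨Δr_i · Δr_j⟩ / ( ⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩ )^{1/2}

with Δr the Cα displacement from its ensemble mean and ⟨·⟩ the frame
average.  The denominator uses ensemble averages: a frame-wise denominator
would not be a correlation coefficient and could not be bounded in [−1, 1].
An atom with exactly zero displacement variance makes C undefined and is an
error; a matrix in which >90% of |C| exceeds 0.99 is flagged with a warning
as rigid-body-dominated.  Results are clipped to [−1, 1] and symmetrised
against roundoff, and agree with the bio3d reference implementation (the
field-standard R package) to ~1e-15 on shared input.

The conventional preprocessing is superposition on the **first frame**
(intentionally different from the mean-structure alignment used for PCA;
both conventions are standard for their respective stages).  This is
exposed as `dccm.align_to_first` because the two input classes differ:

* a real trajectory carries rigid-body drift that must be removed;
* the synthetic generator emits every frame in one laboratory frame, and
  fitting such an ensemble *changes* the planted correlations — the fit
  subtracts each frame's best rigid transform, which removes the shared
  (translational) displacement factors and introduces compensating
  anti-correlation between blocks (measured at ⟨C⟩ ≈ −0.5 between two
  equal blocks).  Planted-value comparisons therefore run unaligned, while
  the community-recovery benchmark keeps the default alignment on to show
  recovery survives it.

## Contact filtering and the residue network

An entry survives iff |C_ij| ≥ 0.5 **and** the residue pair's Cα–Cα
distance is ≤ 10 Å in at least 75% of frames.  The occupancy distance is
Cα–Cα, consistent with the coarse-grained representation used everywhere
else in the pipeline.  Masked entries are represented as absent (NaN),
never as zero, so the network builder cannot mistake a filtered pair for a
true zero correlation.  Raising either threshold can only remove edges
(verified as a property test).

Edges carry |C_ij| (used for modularity) and a path weight −log|C_ij|
(strong correlation = short path; the convention of the correlation-network
tooling this pipeline follows).  |C| = 1 is clamped to 1 − 1e-12 with a
warning, since a zero-length edge breaks shortest-path semantics.  Isolated
residues remain in the graph as singleton nodes.

## Communities and centrality

Communities come from Girvan–Newman clustering: repeatedly delete the edge
with the highest weighted edge betweenness, recomputing betweenness after
every deletion (only within the component that changed — the other
components' values cannot have moved).  Every partition produced along the
dendrogram is scored by Newman–Girvan modularity with |C| edge weights, and
the maximum-modularity partition is returned; the initial connected-
components partition participates, so a graph whose components already
match the planted structure is never split further without a modularity
gain.  Ties in edge betweenness (within 1e-9) are broken toward the
lexicographically smallest edge, making the outcome independent of node
input order.

Node betweenness counts, for every node, the weighted shortest paths
between all other pairs passing through it; degenerate shortest paths
contribute fractionally (Brandes accumulation — "number of unique shortest
paths" is ambiguous under ties, and the fractional convention is the one an
enumeration oracle can pin down exactly).  Both node and edge betweenness
are validated against exhaustive all-simple-paths enumeration on random
graphs.

Hubs are nominated by a nearest-rank percentile threshold (default 98.5%):
the threshold is the smallest observed value with at least that fraction of
values at or below it — no interpolation, so the rule is exact on small
networks — and the high set contains values strictly above.  A threshold
computed on one profile can be imposed on another; that is how a
wild-type-like run's threshold is applied to a mutant-like run.  Centrality
is computed on a frame window (default: the middle half of the trajectory),
on the rationale that transition-mediating hubs are best seen while the
transition is in progress; the window is a config knob with no further
claim attached.  Community detection uses all frames.

## The synthetic generator

The generator supplies ground truth that real trajectories cannot:

* **Block ensembles.**  Per axis, residue i's displacement is
  `sigma_a (sqrt(rho_out) g + sqrt(rho_in − rho_out) b_k(i) + sqrt(1 − rho_in) e_i)`
  with independent standard-normal global, per-block and per-residue
  factors.  The implied correlation is exactly rho_in within and rho_out
  across blocks — also for the 3-D dot-product correlation — and the
  construction is positive semi-definite precisely when
  0 ≤ rho_out ≤ rho_in ≤ 1 (negative target correlations are outside this
  generator's scope).  Sampling is O(N) per frame and the target matrix is
  analytic, which a Cholesky-of-3N-covariance route would not give so
  transparently.
* **Geometry.**  Blocks are compact serpentine lattices (all consecutive
  Cα–Cα steps exactly 3.8 Å) joined by straight 4-residue linkers; lobe
  bodies are separated by 19 Å, so the 10 Å/75% contact filter keeps
  within-block edges and cuts spatially distant pairs.  Without this
  contiguity, contact filtering would confound community recovery.
* **Hinge ensembles.**  One lobe rotates about an axis through the linker
  midpoint by a per-frame angle ~ Normal(0, 5°), plus 0.1 Å isotropic
  jitter; an optional independent twist mode creates the "different
  dominant motion" contrast.  The drawn angle series is returned, so PC
  scores can be checked against the true collective coordinate.

Study conditions used by the benchmarks (fixed once): community recovery on
two 20-residue blocks, rho_in = 0.9, rho_out = 0.05, sigma = 0.5 Å,
F = 2000; replicate RMSIP on blocks of 15/20/25/30 with anisotropic sigma;
the coupled/decoupled contrast on six 16-residue blocks (116 residues with
linkers — large enough that a 98.5% threshold can leave a non-empty high
set, since ⌈0.985 N⌉ < N requires N ≥ 67) with rho_in/rho_out = 0.9/0.6
versus 0.7/0.05; sampling-error checks at F = 5000.

What the generator does **not** emulate: anharmonicity, multi-state
kinetics, solvent coupling, side-chain packing, or any force-field physics.
Passing benchmarks show the statistical machinery is correct and that
planted structure of realistic magnitude survives the full pipeline; they
do not show that any particular biological trajectory has such structure.

## Determinism

Every random draw flows from an explicit integer seed; there is no global
RNG state.  Floats in output tables are written via `repr`, iteration
orders are sorted, and the persisted run log contains no timestamps, so two
runs with the same config and seed produce byte-identical output trees.

## Known limitations

* Negative planted correlations are not supported by the factor generator.
* Girvan–Newman is the only community method (no Louvain/Leiden), matching
  the analysis this pipeline reproduces; it is O(E²·V log V)-ish and
  comfortable up to a few hundred residues, not thousands.
* Contact occupancy is Cα–Cα only; all-atom contact definitions are not
  implemented.
* Binary trajectory formats (DCD/XTC) and mmCIF are not read; convert to
  multi-model PDB or xyz-frames first.
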