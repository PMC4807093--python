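# mdcna — correlation-network analysis of MD coordinate ensembles

Kinase domains are activated not by a single contact but by coordinated
motion: an active kinase shows correlated fluctuations that span both lobes
of the domain, and single point mutations can silence catalysis by
decoupling those motions rather than by breaking the fold.  The standard
computational readout of this "dynamic allostery" is a pipeline over an MD
trajectory: superpose frames and monitor RMSD/distances, extract dominant
collective motions by Cα principal component analysis, build a dynamic
cross-correlation matrix (DCCM), filter it into a residue interaction
network, cluster the network into communities of concerted motion, and rank
residues by node-betweenness centrality to nominate allosteric hubs.

`mdcna` is a tested, reusable implementation of that pipeline for
structural bioinformaticians who want the machinery without gluing together
one-off scripts, plus a synthetic-ensemble generator with *planted* ground
truth (block-structured correlations, hinge-bending motion) so every stage
can be validated quantitatively without any trajectory data.

The quantities at the core:

* **DCCM**: `C_ij = ⟨Δr_i·Δr_j⟩ / (⟨|Δr_i|²⟩⟨|Δr_j|²⟩)^(1/2)` over Cα
  displacements Δr from the ensemble mean; C_ij ∈ [−1, 1].
* **Network filter**: keep pairs with `|C_ij| ≥ 0.5` that stay within 10 Å
  (Cα–Cα) for ≥ 75% of frames; edge path weight `−log|C_ij|`.
* **Communities**: Girvan–Newman edge-betweenness clustering, returning the
  maximum-modularity partition of the dendrogram.
* **Hubs**: weighted node-betweenness centrality with a nearest-rank
  percentile threshold (default 98.5%); a reference run's threshold can be
  imposed on a second run for paired wild-type/mutant comparisons.
* **Subspace overlap**: RMSIP between the first 10 PCs of two ensembles.

## Worked example

Generate a two-block ensemble (44 residues, 2000 frames, within-block
correlation 0.9, cross-block 0.05), analyse it, and compare two runs:

```bash
cat > design.yaml <<EOF
type: block
EOF
mdcna generate --design design.yaml --seed 5 --out gen/

cat > config.yaml <<EOF
input:
  topology: gen/topology.pdb
  trajectory: gen/trajectory.xyz
  format: xyz-frames
out_dir: run1
seed: 5
EOF
mdcna analyze --config config.yaml
```

`run1/` then contains `rmsd.tsv`, `pca_variance.tsv`, `projections.tsv`,
`dccm.txt`, `occupancy.txt`, `network_edges.tsv`, `communities.tsv`,
`centrality.tsv`, `summary.tsv` and a parameter log.  The same pipeline is
available as a library (`mdcna.run_pipeline(RunConfig(...))`).

The numbered drivers under `analysis/` run the package's synthetic study.
For example `python analysis/03_essential_dynamics.py --seed 1` prints

```
hinge PC1 captures 78.00% of the variance; |corr(PC1 score, angle)| = 0.999
replicate RMSIP (first 10 PCs):
  rep1 vs rep2: 0.998
  rep1 vs rep3: 0.993
  rep2 vs rep3: 0.996
```

i.e. the planted opening–closing motion dominates PC1 and its score is the
hinge angle, and independent draws from one planted covariance agree on
their dominant 10-PC subspace.  `python analysis/05_compare_designs.py`
contrasts a "coupled" design (strong within- and cross-block correlation)
with a "decoupled" one (weakened within-block, no cross-block):

```
decoupling lowers inter-community coupling 15.48 -> 0.00 and shrinks the
shared-threshold hub set 1 -> 0
```

— the network-level signature of an inactivating mutation: communities
survive but their couplings vanish, and the bridging hub disappears under
the reference threshold.

## Layout

```
src/mdcna/        ensemble_io, geometry, pca, dccm, network, synthetic,
                  pipeline, cli
analysis/         numbered narrative drivers for the synthetic study
tests/            pytest suite with independent brute-force oracles
docs/methods.md   models, conventions, numerical choices, limitations
```
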