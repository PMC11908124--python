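# allodyn

Dynamical network analysis of protein conformational ensembles — for
structural biologists and computational chemists who want to go from an MD
trajectory (or a synthetic ensemble with known ground truth) to fluctuation
statistics, correlation networks, allosteric pathways, and binding-energy
bookkeeping with a single, fully deterministic toolchain.

The package grew out of the kind of question asked about closely related
kinase paralogs such as CDK4 and CDK6: two proteins with nearly identical
structures can carry very different allosteric wiring between, say, the
β3-αC loop and the glycine-rich G-loop, and that wiring — not the static
fold — decides activity and inhibitor response. allodyn implements the
full analysis chain used to expose such differences, exercised end to end
on synthetic ensembles whose correlation structure is planted and therefore
known exactly.

## What it computes

Given frames **r**(t) over a Cα selection:

- **Superposition & fluctuations** — least-squares (Kabsch) rigid fit of
  every frame to an iteratively refined mean structure; RMSF_i =
  √⟨|Δr_i|²⟩; Cartesian PCA of the 3N×3N covariance with variance
  fractions and per-residue loading profiles.
- **DCCM** — the dynamic cross-correlation matrix
  c_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) ∈ [−1, 1], per replicate and
  averaged across replicates.
- **Protein structure network** — residues as nodes; edges gated by spatial
  contact (Cα within 5 Å by default) and/or a correlation threshold
  (|c| ≥ 0.5 by default for the community graph), weighted w_ij = −ln|c_ij|
  so strongly coupled pairs are *short*.
- **Communities** — divisive Girvan–Newman (remove the highest
  edge-betweenness edge, betweenness on weighted shortest paths), returning
  the partition of maximal modularity along the removal sequence.
- **Allosteric paths** — the optimal (minimum total weight) and top-k
  suboptimal simple paths between a source and a sink residue, with the
  path length L = Σ w_ij, its histogram/KDE peak, and per-node path counts.
- **Interactions** — per-frame minimum inter-group distances and
  salt-bridge occupancy (min N···O ≤ 4 Å between a Lys/Arg/His and an
  Asp/Glu).
- **Binding free energy** — end-point bookkeeping
  ΔG_b = ⟨ΔE_MM⟩ + ⟨ΔG_sol⟩ − TΔS with complex − receptor − ligand
  differences on shared frames, Sackur–Tetrode/rigid-rotor/quasi-harmonic
  entropy, replicate mean ± sd, and a pluggable per-frame energy backend
  (a closed-form toy model ships for verification; production GB/SA models
  plug in behind the same contract).
- **Synthetic ensembles** — Gaussian Cα ensembles whose *population* DCCM
  equals a prescribed target exactly, with planted correlation blocks
  (community ground truth) and planted high-correlation chains (pathway
  ground truth).

## Worked example

`examples/04_allosteric_paths.py` plants a correlation-0.9 chain
2 → 6 → 9 → 13 against a 0.1 background, samples 2000 frames, and searches
the −ln|c| network:

```
planted chain:   [2, 6, 9, 13]
optimal path:    [2, 6, 9, 13]  (L = 1.000)
next suboptimal routes:
  L = 1.982  [2, 6, 13]
  L = 2.036  [2, 9, 13]
  L = 2.979  [2, 13]
path-length peak: 4.875 (histogram), 4.757 (KDE)
most-visited nodes: [(2, 25), (13, 25), (6, 9), (9, 7)]
```

The optimal path recovers the planted chain with total length
3 × (−ln 0.72) ≈ 1.0 (the planted 0.9 relaxes to ≈ 0.72 when the target is
projected to the nearest valid correlation matrix). Skipping a chain node
costs a long background edge, which is why the first suboptimal routes are
roughly one −ln(0.1·…) step longer, and the source/sink appear in all 25
paths while interior chain nodes mediate most of them.

The other examples cover DCCM recovery, RMSF/PCA, community detection,
binding free energies, and the full pipeline; each prints what the numbers
mean. The config-driven pipeline is also available from the shell:

```bash
allodyn validate configs/cdk6_like.json
allodyn run configs/cdk6_like.json --out out/
allodyn paths out/psn_edges.tsv --source A51 --sink A23 --k 100
```

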