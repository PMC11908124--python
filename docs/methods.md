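# Methods

This note records the models, conventions, and numerical choices behind
allodyn, and what the synthetic ground truth does and does not establish
about real trajectories.

## Synthetic ensembles and what they emulate

The generator (`synthetic.sample_ensemble`) draws, per frame, three
independent N-vectors x, y, z from N(0, R) and displaces residue i by
σ_i·(x_i, y_i, z_i)/√3 about a fixed reference geometry (extended chain,
3.8 Å Cα spacing, or ideal α-helix: 1.5 Å rise, 2.3 Å radius,
100°/residue). Imposing the same correlation independently on each
Cartesian axis makes two quantities exact by construction: the population
DCCM equals R, and RMSF_i = σ_i. That exactness is the point — every
downstream stage can be checked against planted truth — but it costs
realism: there is no inertia, no anharmonicity, no side chains, and no
coupling between axes. Passing the recovery tests therefore demonstrates
the *estimators and graph machinery* are correct, not that any biological
conclusion transfers; on real MD the DCCM additionally inherits
superposition artifacts (below) and finite-sampling correlation between
frames.

Defaults: σ = 0.5 Å (a typical well-ordered-residue RMSF), 2000 frames per
replicate and three replicates in pipeline configs (mirroring a saved-frame
MD budget at which sampling error ≈ 0.02–0.03 per DCCM entry), seeds
explicit everywhere — generators are pure functions of (spec, seed).

Target matrices (planted blocks, planted chains) are projected to the
nearest valid correlation matrix by clamping negative eigenvalues,
reconstructing, and rescaling the diagonal to 1. The repair is
deterministic and order-independent; its largest entrywise change is
recorded on the spec (`repair_bound`). One consequence worth knowing: an
isolated chain of 0.9–0.95 correlations over a near-zero background is far
from positive semidefinite (its transitive correlations are missing), so
the planted entries relax to ≈ 0.65–0.75 after repair. They remain the
dominant off-diagonal structure, which is what path recovery relies on.

## Superposition and its interaction with planted correlations

Frames are superposed by a closed-form Kabsch fit over the analysis
selection, by default onto an iteratively refined mean structure
(convergence 1e-6 Å, cap 50 iterations); first-frame and external
references are available for convention-sensitive comparisons. Fewer than
three non-collinear atoms leave the rotation underdetermined and raise.

Least-squares fitting removes six rigid-body degrees of freedom, and with
them any *collective* displacement shared by most residues. On a planted
two-block ensemble with in-block correlation 0.6 we measured the in-block
DCCM dropping to ≈ 0.13 after fitting — the block motion looks like rigid
motion and is subtracted. This is a genuine property of superposition-based
DCCMs, not a bug. The generator emits frames already in a common reference
frame, so ground-truth recovery computes the DCCM directly on the generated
frames, and the pipeline exposes `superpose` as a config switch: true
(default) for real trajectories, false in the shipped synthetic
configuration.

## DCCM and replicate handling

c_ij uses the 3-D dot-product form ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) with
population (1/F) normalization, diagonal pinned to exactly 1, entries
clamped to [−1, 1] only within 1e-12 (larger violations raise). A residue
whose variance is below 1e-12 of the largest is reported by name —
correlation is undefined for frozen coordinates. Replicates are combined by
entrywise averaging of per-replicate DCCMs (concatenation is available by
passing a merged ensemble); the pipeline discards the first half of each
trajectory as equilibration by default (`equilibration_fraction = 0.5`).

## Networks, communities, paths

Edges require spatial contact (mean-structure Cα distance ≤ 5 Å by
default; an occupancy mode — within cutoff in ≥ θ of frames — is
available) and/or a correlation-magnitude threshold. The community graph
uses |c| ≥ 0.5 and no contact gate by default; the path network uses the
contact gate and no threshold. Both gates are configurable because the two
constructions serve different questions (coarse co-moving bodies vs. signal
routes). Weights are w = −ln|c| with |c| floored at 1e-6 (weights stay
finite; pairs below the floor are dropped). The magnitude |c| is used
rather than signed c so that anti-correlated pairs get real, strong-coupling
weights.

Girvan–Newman removes the highest edge-betweenness edge (betweenness on
weighted shortest paths, ties broken by lexicographically smallest edge),
records the partition sequence, and returns the partition maximizing
modularity. Modularity treats edge values as affinities, so it is computed
on |c_ij| (attribute `corr`), not on the distance −ln|c|; plain graphs
without that attribute fall back to unweighted modularity. Using the
distance as an affinity would reward cutting exactly the wrong edges.

Suboptimal paths use networkx's Yen-type `shortest_simple_paths`
enumeration; paths are collected until the k-th length is strictly exceeded
(margin 1e-12), then sorted by (length, node sequence) and truncated, which
makes tie order bit-reproducible and lets the output match brute-force
enumeration exactly on small graphs. The path-length distribution uses a
fixed-width histogram (0.05 default) anchored at the minimum length, peak =
center of the max-count bin, leftmost on ties; a Gaussian-KDE mode is
reported alongside because "the peak" of a path-length distribution is
convention-dependent.

The shipped `configs/cdk6_like.json` analyzes a 60-residue helix with two
planted 30-residue blocks and a planted source→sink chain (a synthetic
analog of a β3-αC-loop → G-loop route), k = 100. It sets the contact
cutoff to 8 Å: on a Cα-only ideal helix a 5 Å cutoff keeps only |i−j| = 1
pairs (a path graph with a single simple path), while 8 Å restores roughly
the contact degree that 5 Å yields on a real all-atom kinase. The RunConfig
default remains 5 Å.

## Interactions

Salt-bridge occupancy is the fraction of frames with min N···O ≤ 4 Å
between the charged side-chain nitrogens (Lys NZ; Arg NE/NH1/NH2; His
ND1/NE2) and carboxylate oxygens (Asp OD1/OD2; Glu OE1/OE2). The 4 Å
heavy-atom criterion is the common convention and is config-exposed.
Cα-only models cannot host this statistic; the error says so explicitly and
points to the generic minimum-distance series with caller-chosen groups.

## Binding free energy

Single-trajectory protocol: receptor and ligand terms are evaluated on the
complex's frames, so internal (bonded) energies cancel identically and
⟨ΔE_MM⟩ + ⟨ΔG_sol⟩ reduces to the cross-chain interaction averages over the
analysis window (final half of frames by default). ΔG_b =
⟨ΔE_MM⟩ + ⟨ΔG_sol⟩ − TΔS holds as an exact identity of the stored parts;
replicates are reported as mean ± sample sd. T defaults to 310 K.

The per-frame physical energy is a pluggable callable
`(topology, frame coords, atom subset) → EnergyTerms`. The shipped toy
model — Coulomb k·q_iq_j/(ε r) with k = 332.0636 kcal·Å/(mol·e²), 12-6
Lennard-Jones with Lorentz–Berthelot mixing, linear per-atom solvation
increments — exists to make every number hand-checkable (±1 e at 5 Å gives
−66.41 kcal/mol); it is not a physical solvation model, and generalized-Born
/ surface-area backends are expected to be supplied by the caller behind the
same contract.

Entropy: S_trans from Sackur–Tetrode (1 atm, standard atomic masses),
S_rot from the rigid rotor on the mean structure (symmetry number 1;
collinear subsets handled as linear rotors with two rotational modes;
point-like subsets raise), S_vib quasi-harmonic: eigenvalues λ_k of the
mass-weighted coordinate covariance give ω_k = √(k_BT/λ_k) and each mode
contributes the quantum harmonic-oscillator entropy; the six
largest-λ (lowest-frequency) modes are skipped as rigid-body motion and
near-zero eigenvalues contribute nothing, so a frozen ensemble has
S_vib = 0 exactly. Constants: k_B = 0.0019872041 kcal/mol/K; SI values from
scipy.constants. Normal-mode (Hessian-based) entropies are out of scope.

## Determinism and degenerate inputs

All tie-breaks are lexicographic (edges in Girvan–Newman, path ordering);
PCA eigenvector signs are fixed by making each component's
largest-magnitude entry positive; every sampler takes an explicit seed and
no stage uses global random state. Pipeline outputs are byte-identical for
a fixed config (verified by hashing in the tests); `report.json` carries
wall-clock timings and is excluded from that comparison. Degenerate inputs
fail loudly rather than silently: empty selections, zero-variance residues,
disconnected source/sink pairs, insertion codes in PDB files, non-PSD
targets beyond repair, single-frame fluctuation statistics.

## Problem sizes

Test and acceptance workloads use 10–60 residue ensembles with 200–5000
frames, ≤ 10-node graphs for brute-force oracle comparisons, and 20–30-node
planted-partition networks — sizes at which exhaustive oracles are exact
and the full suite runs in well under a minute apiece. The machinery itself
is vectorized over frames and scales to kinase-sized selections (~300
residues); Girvan–Newman's repeated betweenness recomputation is the
practical bottleneck on dense graphs.

## Known limitations

- The generator's axis-isotropic construction cannot plant anisotropic or
  time-lagged correlation; tICA-style analyses are out of scope.
- Community detection is exact Girvan–Newman, not a scalable heuristic; on
  graphs with thousands of edges it is slow by design.
- The toy energy model has no dielectric screening beyond a constant, no
  cutoffs, and one-body solvation only; it validates bookkeeping, not
  energetics.
- PDB insertion codes and multi-conformer residues beyond highest-occupancy
  selection are unsupported.
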