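"""Binding free energy bookkeeping on the toy two-chain complex.

Two 3-residue chains 5 Å apart interact through a closed-form pairwise model
(Coulomb + Lennard-Jones + per-atom solvation increments).  The end-point
estimate assembles dG_b = <dE_MM> + <dG_sol> - T*dS on the same frames for
complex and parts, so internal terms cancel exactly; entropy combines
Sackur–Tetrode translation, rigid-rotor rotation, and quasi-harmonic
vibration.
"""

import numpy as np

from allodyn import (AtomSelection, ToyComplexSpec, TrajectoryEnsemble,
                     binding_free_energy, make_toy_complex)

spec = ToyComplexSpec(n_res_a=3, n_res_b=3, separation=5.0,
                      charges=np.array([1.0, 0.0, -1.0, -1.0, 0.0, 1.0]),
                      lj_epsilon=0.1)
structure, model = make_toy_complex(spec)

# three replicates: small independent thermal jitter about the complex geometry
trajs = []
for seed in (1, 2, 3):
    rng = np.random.default_rng(seed)
    frames = structure.coords[None] + rng.normal(0, 0.05, (50, 6, 3))
    trajs.append(TrajectoryEnsemble(topology=structure, frames=frames,
                                    replicate=seed))

receptor = AtomSelection(indices=np.arange(3), label="chain A")
ligand = AtomSelection(indices=np.arange(3, 6), label="chain B")
bfe = binding_free_energy(trajs, receptor, ligand, model, temperature=310.0)

s = bfe.summary()
for name in ("dE_MM", "dG_sol", "minus_TdS", "dG_b"):
    print(f"{name:>10s}: {s[name]['mean']:9.3f} ± {s[name]['sd']:.3f} kcal/mol")
print(f"identity residual: "
      f"{np.abs(bfe.dG_b - (bfe.dE_MM + bfe.dG_sol - bfe.TdS)).max():.1e}")
# dG_sol is exactly 0 here: the toy solvation terms are one-body increments
# and cancel in the complex-minus-parts difference by construction.
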