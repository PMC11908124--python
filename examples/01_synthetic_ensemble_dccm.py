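"""Generate a synthetic ensemble with planted correlation blocks and recover
the dynamic cross-correlation matrix (DCCM) from it.

The generator draws Gaussian Cα displacements whose population DCCM equals
the prescribed target exactly, so the estimation error printed below is pure
sampling noise.
"""

import numpy as np

from allodyn import (EnsembleSpec, dccm, make_block_correlation, sample_ensemble,
                     select)

# two groups of 10 residues moving together (c=0.8 inside, 0.1 across)
R = make_block_correlation(20, [set(range(10)), set(range(10, 20))],
                           rho_in=0.8, rho_out=0.1)

spec = EnsembleSpec(n_residues=20, amplitudes=0.5, target_correlation=R,
                    n_frames=3000, seed=7)
traj = sample_ensemble(spec)
sel = select(traj.topology, "calpha")
c = dccm(traj, sel)

err = np.abs(c.values - R)
print(f"frames sampled:            {traj.n_frames}")
print(f"in-block correlation:      {c.values[2, 7]:+.3f}  (target +0.800)")
print(f"cross-block correlation:   {c.values[2, 15]:+.3f}  (target +0.100)")
print(f"max |estimate - target|:   {err.max():.4f}")
print(f"mean |estimate - target|:  {err[~np.eye(20, dtype=bool)].mean():.4f}")
# The max error shrinks as 1/sqrt(n_frames): the DCCM estimator is unbiased
# here because the ensemble is generated in a fixed reference frame.
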