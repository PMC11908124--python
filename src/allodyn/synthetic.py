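"""Synthetic conformational ensembles with known correlation structure.

Generators here produce Gaussian Cα ensembles whose *population* dynamic
cross-correlation matrix equals a prescribed target R exactly, so every
downstream stage (DCCM estimation, community detection, suboptimal path
search) can be tested against planted ground truth instead of real MD.

Construction: for each frame, three independent N-vectors x, y, z are drawn
from N(0, R); the displacement of residue i is sigma_i * (x_i, y_i, z_i) / sqrt(3)
added to the reference geometry.  Because the same correlation is imposed
identically and independently on each Cartesian axis,

    <dr_i . dr_j> = sigma_i sigma_j R_ij,

so the normalized DCCM of the population is R and the per-residue RMSF is
sigma_i.  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import AtomSelection, StructureModel, TrajectoryEnsemble

__all__ = [
    "EnsembleSpec",
    "ToyComplexSpec",
    "make_reference_geometry",
    "make_block_correlation",
    "plant_chain_correlation",
    "nearest_correlation_psd",
    "sample_ensemble",
    "make_toy_complex",
]

_PSD_TOL = 1e-8


def nearest_correlation_psd(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Negative eigenvalues are clamped to zero, the matrix is reconstructed,
    and the diagonal rescaled back to 1.  Returns the repaired matrix and
    the largest absolute entrywise change it introduced.
    """
    R = np.asarray(R, dtype=float)
    sym = 0.5 * (R + R.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= -_PSD_TOL:
        repaired = sym.copy()
        np.fill_diagonal(repaired, 1.0)
        return repaired, float(np.abs(repaired - R).max())
    clamped = np.clip(vals, 0.0, None)
    repaired = (vecs * clamped) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    if np.any(d <= 0):
        raise ValueError("PSD repair produced a zero-variance row; target is degenerate")
    repaired = repaired / np.outer(d, d)
    repaired = 0.5 * (repaired + repaired.T)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.abs(repaired - R).max())


@dataclass
class EnsembleSpec:
    """Recipe for a synthetic Gaussian Cα ensemble."""

    n_residues: int
    geometry: str = "extended-chain"          # or "ideal-helix"
    amplitudes: np.ndarray | float = 0.5      # sigma_i, Å
    target_correlation: np.ndarray | None = None  # N×N; identity if None
    n_frames: int = 1000
    seed: int = 0
    community_labels: np.ndarray | None = None
    planted_chain: Sequence[int] | None = None
    repair_bound: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        sig = np.broadcast_to(np.asarray(self.amplitudes, dtype=float),
                              (self.n_residues,)).copy()
        if np.any(sig < 0):
            raise ValueError("amplitudes must be non-negative")
        self.amplitudes = sig
        if self.target_correlation is None:
            self.target_correlation = np.eye(self.n_residues)
        R = np.asarray(self.target_correlation, dtype=float)
        if R.shape != (self.n_residues, self.n_residues):
            raise ValueError("target correlation has wrong shape")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("target correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("target correlation must have unit diagonal")
        if np.abs(R).max() > 1 + 1e-10:
            raise ValueError("target correlation entries must lie in [-1, 1]")
        R, self.repair_bound = nearest_correlation_psd(R)
        self.target_correlation = R


def make_reference_geometry(n_residues: int, geometry: str = "extended-chain",
                            seed: int = 0) -> StructureModel:
    """Cα-only reference chain.

    ``extended-chain`` places residues 3.8 Å apart on the x axis;
    ``ideal-helix`` uses a 1.5 Å rise, 2.3 Å radius and 100°/residue twist.
    The geometry is deterministic; ``seed`` is accepted for interface
    symmetry with the samplers and ignored.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if geometry == "extended-chain":
        coords = np.zeros((n_residues, 3))
        coords[:, 0] = 3.8 * np.arange(n_residues)
    elif geometry == "ideal-helix":
        t = np.deg2rad(100.0) * np.arange(n_residues)
        coords = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t),
                                  1.5 * np.arange(n_residues, dtype=float)])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    n = n_residues
    return StructureModel(
        atom_name=np.array(["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        res_number=np.arange(1, n + 1),
        res_name=np.array(["ALA"] * n, dtype=object),
        hetero=np.zeros(n, dtype=bool),
        coords=coords,
    )


def make_block_correlation(n_residues: int, blocks: Sequence[Sequence[int]],
                           rho_in: float, rho_out: float) -> np.ndarray:
    """Planted-partition correlation target.

    R_ij = 1 on the diagonal, ``rho_in`` inside a block, ``rho_out`` across
    blocks; repaired to PSD afterwards.  ``blocks`` must partition
    ``range(n_residues)``.
    """
    if not (0 <= rho_out < rho_in <= 1):
        raise ValueError("require 0 <= rho_out < rho_in <= 1")
    flat = sorted(i for b in blocks for i in b)
    if flat != list(range(n_residues)):
        raise ValueError("blocks must partition the residue index set")
    R = np.full((n_residues, n_residues), rho_out)
    for b in blocks:
        b = np.asarray(sorted(b))
        R[np.ix_(b, b)] = rho_in
    np.fill_diagonal(R, 1.0)
    R, _ = nearest_correlation_psd(R)
    return R


def plant_chain_correlation(base: np.ndarray, chain: Sequence[int],
                            rho_chain: float) -> np.ndarray:
    """Plant a high-correlation chain into a correlation target.

    Consecutive pairs along ``chain`` are set to ``rho_chain`` (both
    triangles), then the matrix is repaired to PSD.  Used as ground truth
    for source→sink path recovery: with ``rho_chain`` well above the
    background, the minimum −ln|c| path between the chain ends traverses
    exactly the chain.
    """
    chain = list(chain)
    if len(chain) < 2:
        raise ValueError("chain must contain at least 2 nodes")
    if len(set(chain)) != len(chain):
        raise ValueError("chain nodes must be distinct")
    R = np.array(base, dtype=float)
    for a, b in zip(chain[:-1], chain[1:]):
        R[a, b] = R[b, a] = rho_chain
    R, _ = nearest_correlation_psd(R)
    return R


def sample_ensemble(spec: EnsembleSpec) -> TrajectoryEnsemble:
    """Draw a seeded Gaussian ensemble whose population DCCM equals the target."""
    ref = make_reference_geometry(spec.n_residues, spec.geometry, spec.seed)
    R = spec.target_correlation
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < -_PSD_TOL:
        raise ValueError("target correlation is not PSD after repair")
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))  # R = factor @ factor.T
    rng = np.random.default_rng(spec.seed)
    # (F, 3, N) standard normals -> correlated along the residue axis
    z = rng.standard_normal((spec.n_frames, 3, spec.n_residues))
    corr = z @ factor.T                               # each axis ~ N(0, R)
    disp = (spec.amplitudes / np.sqrt(3.0)) * corr     # scale per residue
    frames = ref.coords[None, :, :] + np.transpose(disp, (0, 2, 1))
    return TrajectoryEnsemble(topology=ref, frames=frames, replicate=spec.seed)


@dataclass
class ToyComplexSpec:
    """Two Cα-level chains plus a closed-form pairwise energy model.

    Chain A lies on the x axis; chain B is a parallel chain offset by
    ``separation`` Å in y.  Per-atom parameters are ordered chain A first.
    """

    n_res_a: int
    n_res_b: int
    separation: float = 5.0
    charges: np.ndarray | float = 0.0
    lj_epsilon: np.ndarray | float = 0.0   # kcal/mol well depths
    lj_sigma: np.ndarray | float = 3.5     # Å
    solv_polar: np.ndarray | float = 0.0   # kcal/mol per-atom increments
    solv_nonpolar: np.ndarray | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res_a < 1 or self.n_res_b < 1:
            raise ValueError("both chains must be non-empty")
        n = self.n_res_a + self.n_res_b
        for name in ("charges", "lj_epsilon", "lj_sigma", "solv_polar", "solv_nonpolar"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (n,)).copy()
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.n_res_a + self.n_res_b


def make_toy_complex(spec: ToyComplexSpec):
    """Build the two-chain structure and its toy energy model.

    Returns ``(StructureModel, ToyEnergyModel)``; the model satisfies the
    pluggable per-frame energy contract used by the energetics module and
    every term is hand-checkable (plain Coulomb, 12-6 Lennard-Jones with
    Lorentz–Berthelot mixing, linear per-atom solvation increments).
    """
    from .energetics import ToyEnergyModel

    na, nb = spec.n_res_a, spec.n_res_b
    coords = np.zeros((na + nb, 3))
    coords[:na, 0] = 3.8 * np.arange(na)
    coords[na:, 0] = 3.8 * np.arange(nb)
    coords[na:, 1] = spec.separation
    n = na + nb
    structure = StructureModel(
        atom_name=np.array(["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        chain_id=np.array(["A"] * na + ["B"] * nb, dtype=object),
        res_number=np.concatenate([np.arange(1, na + 1), np.arange(1, nb + 1)]),
        res_name=np.array(["ALA"] * n, dtype=object),
        hetero=np.zeros(n, dtype=bool),
        coords=coords,
    )
    model = ToyEnergyModel(
        charges=spec.charges, lj_epsilon=spec.lj_epsilon, lj_sigma=spec.lj_sigma,
        solv_polar=spec.solv_polar, solv_nonpolar=spec.solv_nonpolar,
    )
    return structure, model


def chain_selections(structure: StructureModel) -> dict[str, AtomSelection]:
    """One AtomSelection per chain id, in chain order."""
    out = {}
    for c in dict.fromkeys(str(x) for x in structure.chain_id):
        idx = np.nonzero(np.asarray(structure.chain_id) == c)[0]
        out[c] = AtomSelection(indices=idx, label=f"chain={c}")
    return out
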