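"""Superposition, fluctuation statistics, and Cartesian PCA of Cα ensembles.

Superposition is a least-squares rigid-body (Kabsch) fit of every frame onto
a reference over a chosen atom selection; by default the reference is the
iteratively refined mean structure, which removes the bias of fitting to an
arbitrary single frame.  PCA is the eigendecomposition of the 3N×3N
coordinate covariance (unweighted — Cα masses are all equal), with a fixed
sign convention so loading profiles are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AtomSelection, StructureModel, TrajectoryEnsemble

__all__ = [
    "SuperpositionResult",
    "PCAResult",
    "superpose",
    "mean_structure",
    "rmsf",
    "pca",
    "residue_loadings",
    "kabsch",
]


@dataclass
class SuperpositionResult:
    rotations: np.ndarray      # (F, 3, 3)
    translations: np.ndarray   # (F, 3)
    rmsd: np.ndarray           # (F,) Å, over the fitted selection
    reference: np.ndarray      # (n_sel, 3) reference coordinates used
    iterations: int = 1


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``target``.

    Returns (R, t, cm) such that ``(x - cm) @ R.T + t`` superposes the mobile
    points; R is a proper rotation (det +1).
    """
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, ct, cm


def _check_fittable(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8:
        raise ValueError("selected atoms are collinear; rotation is underdetermined")


def superpose(
    traj: TrajectoryEnsemble,
    selection: AtomSelection,
    reference: str | np.ndarray | StructureModel = "mean",
    iterate: bool = True,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[TrajectoryEnsemble, SuperpositionResult]:
    """Rigid-body fit every frame onto a reference over ``selection``.

    ``reference`` may be ``"first-frame"``, ``"mean"`` (iteratively refined
    mean structure), an explicit (n_sel, 3) coordinate array, or a
    :class:`StructureModel`.  All atoms are transformed; the fit itself uses
    only the selection.
    """
    sel = selection.indices
    frames = traj.frames
    if reference == "first-frame":
        ref = frames[0, sel].copy()
        do_iterate = False
    elif reference == "mean":
        ref = frames[0, sel].copy()
        do_iterate = iterate
    elif isinstance(reference, StructureModel):
        ref = reference.coords[sel].copy()
        do_iterate = False
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (len(sel), 3):
            raise ValueError("external reference must have the selection's shape")
        do_iterate = False
    _check_fittable(ref)

    n_iter = 0
    while True:
        n_iter += 1
        F = frames.shape[0]
        rotations = np.empty((F, 3, 3))
        translations = np.empty((F, 3))
        fitted = np.empty_like(frames)
        for f in range(F):
            R, ct, cm = kabsch(frames[f, sel], ref)
            fitted[f] = (frames[f] - cm) @ R.T + ct
            rotations[f] = R
            translations[f] = ct - cm @ R.T
        new_ref = fitted[:, sel].mean(axis=0)
        if not do_iterate or n_iter >= max_iter or np.abs(new_ref - ref).max() < tol:
            break
        ref = new_ref

    diffs = fitted[:, sel] - ref
    rmsd = np.sqrt((diffs ** 2).sum(axis=(1, 2)) / len(sel))
    out = TrajectoryEnsemble(topology=traj.topology.with_coords(fitted[0]),
                             frames=fitted, times=traj.times, replicate=traj.replicate)
    return out, SuperpositionResult(rotations=rotations, translations=translations,
                                    rmsd=rmsd, reference=ref, iterations=n_iter)


def mean_structure(traj: TrajectoryEnsemble, selection: AtomSelection | None = None) -> np.ndarray:
    """Arithmetic per-atom mean coordinates (Å) of a superposed ensemble."""
    if selection is None:
        return traj.frames.mean(axis=0)
    return traj.frames[:, selection.indices].mean(axis=0)


def rmsf(traj: TrajectoryEnsemble, selection: AtomSelection) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the mean position."""
    if traj.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    x = traj.frames[:, selection.indices]
    d = x - x.mean(axis=0)
    return np.sqrt((d ** 2).sum(axis=2).mean(axis=0))


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # (3N,), Å², descending
    eigenvectors: np.ndarray       # (3N, 3N), columns are components
    variance_fractions: np.ndarray
    cumulative_variance: np.ndarray
    mean: np.ndarray               # (3N,) mean coordinates
    covariance: np.ndarray         # (3N, 3N)

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size

    def project(self, traj: TrajectoryEnsemble, selection: AtomSelection,
                components: int | None = None) -> np.ndarray:
        """Frame projections onto the leading components."""
        k = components if components is not None else self.n_components
        X = traj.frames[:, selection.indices].reshape(traj.n_frames, -1)
        return (X - self.mean) @ self.eigenvectors[:, :k]


def pca(traj: TrajectoryEnsemble, selection: AtomSelection,
        window: slice | None = None) -> PCAResult:
    """Cartesian principal component analysis of the selection's coordinates.

    The covariance uses the population normalization (1/F).  Components are
    sorted by descending eigenvalue; each eigenvector's largest-magnitude
    entry is made positive for a deterministic sign.
    """
    frames = traj.frames if window is None else traj.frames[window]
    if frames.shape[0] < 2:
        raise ValueError("PCA needs at least 2 frames")
    X = frames[:, selection.indices].reshape(frames.shape[0], -1)
    mu = X.mean(axis=0)
    Xc = X - mu
    C = Xc.T @ Xc / X.shape[0]
    if not np.all(np.isfinite(C)):
        raise ValueError("covariance matrix contains non-finite entries")
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    # deterministic sign: largest-|entry| of each component made positive
    for k in range(vecs.shape[1]):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    total = vals.sum()
    fractions = vals / total if total > 0 else np.zeros_like(vals)
    return PCAResult(eigenvalues=vals, eigenvectors=vecs,
                     variance_fractions=fractions,
                     cumulative_variance=np.cumsum(fractions),
                     mean=mu, covariance=C)


def residue_loadings(result: PCAResult, component: int) -> np.ndarray:
    """Per-residue contribution to one PC: the norm of its 3-vector block.

    Squared loadings sum to 1 because eigenvectors are unit length.
    """
    if not 0 <= component < result.n_components:
        raise IndexError(f"component {component} out of range")
    v = result.eigenvectors[:, component]
    return np.linalg.norm(v.reshape(-1, 3), axis=1)
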