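"""Dynamic cross-correlation matrices (DCCM) and replicate aggregation.

The DCCM entry for residues i, j is the normalized covariance of their 3-D
displacement vectors about the mean structure,

    c_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

with c_ij in [-1, 1]; +1 is fully correlated motion, -1 fully
anti-correlated.  The dot-product (vector) form is used, not a per-axis
correlation.  Replicates are aggregated by entrywise averaging of their
per-replicate DCCMs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AtomSelection, TrajectoryEnsemble, write_matrix_tsv

__all__ = ["CorrelationMatrix", "dccm", "average_dccm"]

_CLAMP_TOL = 1e-12


@dataclass
class CorrelationMatrix:
    """A residue–residue DCCM with its provenance."""

    values: np.ndarray             # (N, N), symmetric, unit diagonal
    labels: list[str] | None = None
    n_frames: int = 0
    replicate: int | str = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        over = np.abs(v).max() - 1.0
        if over > _CLAMP_TOL:
            raise ValueError(f"correlation entries exceed 1 by {over:.3g}")
        self.values = np.clip(v, -1.0, 1.0)

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def write_tsv(self, path) -> None:
        labels = self.labels or [str(i) for i in range(self.n_residues)]
        write_matrix_tsv(self.values, labels, path)


def dccm(traj: TrajectoryEnsemble, selection: AtomSelection,
         window: slice | None = None, labels: Sequence[str] | None = None) -> CorrelationMatrix:
    """DCCM of a (superposed) ensemble over the selected atoms.

    ``window`` restricts the frames used (e.g. ``slice(F//2, None)`` to
    discard the first half as equilibration); default is all frames.
    """
    frames = traj.frames if window is None else traj.frames[window]
    if frames.shape[0] < 2:
        raise ValueError("DCCM needs at least 2 frames in the window")
    x = frames[:, selection.indices]                  # (F, N, 3)
    d = x - x.mean(axis=0)
    cov = np.einsum("fia,fja->ij", d, d) / d.shape[0]
    var = np.diag(cov).copy()
    # cancellation leaves ~1e-30 rather than exact zero for frozen residues
    if np.any(var <= 1e-12 * max(1.0, float(var.max()))):
        bad = int(np.argmin(var))
        name = labels[bad] if labels else f"index {bad}"
        raise ValueError(f"zero-variance residue {name}: correlation undefined")
    c = cov / np.sqrt(np.outer(var, var))
    over = np.abs(c).max() - 1.0
    if over > _CLAMP_TOL:
        raise ValueError(f"correlation entries exceed 1 by {over:.3g}")
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(values=c, labels=list(labels) if labels else None,
                             n_frames=frames.shape[0], replicate=traj.replicate)


def average_dccm(matrices: Sequence[CorrelationMatrix]) -> CorrelationMatrix:
    """Entrywise mean of per-replicate DCCMs; diagonal re-pinned to 1."""
    if len(matrices) == 0:
        raise ValueError("need at least one matrix to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.n_residues != first.n_residues:
            raise ValueError("matrices cover different selections (size mismatch)")
        if m.labels != first.labels:
            raise ValueError("matrices cover different selections (label mismatch)")
    mean = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(mean, 1.0)
    return CorrelationMatrix(values=mean, labels=first.labels,
                             n_frames=sum(m.n_frames for m in matrices),
                             replicate="averaged")
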