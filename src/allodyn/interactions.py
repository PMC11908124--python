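"""Distance-based interaction statistics across trajectory frames.

Provides a generic minimum inter-group distance series and the salt-bridge
occupancy built on top of it: the fraction of frames in which the closest
charged-group nitrogen–oxygen pair of a basic/acidic residue pair is within
a cutoff (4.0 Å by default, the common heavy-atom salt-bridge convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AtomSelection, TrajectoryEnsemble

__all__ = [
    "DistanceSeries",
    "OccupancyResult",
    "pair_distance_series",
    "salt_bridge_occupancy",
]

# side-chain atoms carrying the formal charge
BASIC_NITROGENS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_OXYGENS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass
class DistanceSeries:
    """Per-frame minimum distance (Å) between two atom groups."""

    values: np.ndarray
    group_a: str = ""
    group_b: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def occupancy(self, cutoff: float) -> float:
        return float(np.mean(self.values <= cutoff))


@dataclass
class OccupancyResult:
    occupancy: float
    cutoff: float
    n_frames: int
    pair: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


def pair_distance_series(traj: TrajectoryEnsemble, group_a: AtomSelection,
                         group_b: AtomSelection) -> DistanceSeries:
    """Per frame, the minimum distance over all cross pairs of two groups."""
    a = set(group_a.indices.tolist())
    b = set(group_b.indices.tolist())
    if a & b:
        raise ValueError("atom groups overlap")
    xa = traj.frames[:, group_a.indices]       # (F, na, 3)
    xb = traj.frames[:, group_b.indices]       # (F, nb, 3)
    diff = xa[:, :, None, :] - xb[:, None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    return DistanceSeries(values=dist.min(axis=(1, 2)),
                          group_a=group_a.label, group_b=group_b.label)


def _residue_atoms(traj: TrajectoryEnsemble, chain: str, resnum: int,
                   wanted: dict[str, tuple[str, ...]]) -> AtomSelection:
    top = traj.topology
    in_res = (np.asarray(top.chain_id) == chain) & (top.res_number == resnum)
    if not in_res.any():
        raise ValueError(f"residue {chain}:{resnum} not found")
    resname = str(np.asarray(top.res_name)[in_res][0])
    if resname not in wanted:
        kinds = "/".join(sorted(wanted))
        raise ValueError(f"residue {chain}:{resnum} is {resname}, expected {kinds}")
    names = wanted[resname]
    idx = np.nonzero(in_res & np.isin(np.asarray(top.atom_name), names))[0]
    if idx.size == 0:
        raise ValueError(
            f"residue {chain}:{resnum} ({resname}) is missing side-chain atoms "
            f"{names}; for reduced (e.g. Cα-only) models use pair_distance_series "
            f"with explicit atom groups instead")
    return AtomSelection(indices=idx, label=f"{chain}:{resname}{resnum}")


def salt_bridge_occupancy(traj: TrajectoryEnsemble, basic: tuple[str, int],
                          acidic: tuple[str, int], cutoff: float = 4.0) -> OccupancyResult:
    """Occupancy of a basic–acidic residue salt bridge across frames.

    ``basic`` and ``acidic`` are (chain id, author residue number) pairs; the
    criterion is min N···O heavy-atom distance <= ``cutoff``.
    """
    n_sel = _residue_atoms(traj, *basic, wanted=BASIC_NITROGENS)
    o_sel = _residue_atoms(traj, *acidic, wanted=ACIDIC_OXYGENS)
    series = pair_distance_series(traj, n_sel, o_sel)
    return OccupancyResult(occupancy=series.occupancy(cutoff), cutoff=cutoff,
                           n_frames=traj.n_frames,
                           pair=f"{n_sel.label}--{o_sel.label}")
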