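"""End-point (MM/GBSA-style) binding free energy bookkeeping.

The binding free energy of a two-chain complex is assembled as

    dG_b = <dE_MM> + <dG_sol> - T*dS

where <dE_MM> is the frame-averaged gas-phase molecular-mechanics
interaction energy (internal + electrostatic + van der Waals), <dG_sol> the
frame-averaged solvation difference (polar + nonpolar), and dS the entropy
difference, each computed as complex − receptor − ligand on the *same*
frames (single-trajectory protocol, so internal terms cancel exactly).

The per-frame physical energy evaluation is pluggable: any callable
``model(topology, frame_coords, atom_indices) -> EnergyTerms`` works.  The
shipped :class:`ToyEnergyModel` (plain Coulomb, 12-6 Lennard-Jones,
per-atom solvation increments) makes the bookkeeping hand-checkable;
production GB/surface-area models can be dropped in behind the same
contract.

Entropy: translational and rotational terms come from the Sackur–Tetrode
and rigid-rotor formulas on the mean structure; the vibrational term is
quasi-harmonic, from the eigenvalues of the mass-weighted coordinate
covariance of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import constants as const

from .core import AtomSelection, StructureModel, TrajectoryEnsemble

__all__ = [
    "EnergyTerms",
    "EntropyTerms",
    "BindingFreeEnergy",
    "ToyEnergyModel",
    "frame_terms",
    "interaction_terms",
    "quasiharmonic_entropy",
    "rigid_body_entropy",
    "binding_free_energy",
    "KB_KCAL",
    "COULOMB_K",
]

KB_KCAL = 0.0019872041          # kcal/mol/K
COULOMB_K = 332.0636            # kcal·Å/(mol·e²)
_AMU = const.atomic_mass        # kg
_ATM = 101325.0                 # Pa

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
}


def atom_masses(structure: StructureModel, indices: np.ndarray) -> np.ndarray:
    """Standard atomic weights (amu) for the given atoms, by element."""
    out = np.empty(len(indices))
    for k, a in enumerate(indices):
        el = str(structure.element[a]).upper()
        if el not in ATOMIC_MASSES:
            raise ValueError(f"no standard mass for element {el!r}")
        out[k] = ATOMIC_MASSES[el]
    return out


@dataclass
class EnergyTerms:
    """Per-frame energy decomposition, kcal/mol."""

    E_internal: float = 0.0
    E_elec: float = 0.0
    E_vdw: float = 0.0
    G_solv_polar: float = 0.0
    G_solv_nonpolar: float = 0.0
    tag: str = ""
    frame: int = -1

    def __post_init__(self) -> None:
        for name in ("E_internal", "E_elec", "E_vdw", "G_solv_polar", "G_solv_nonpolar"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")

    @property
    def E_MM(self) -> float:
        return self.E_internal + self.E_elec + self.E_vdw

    @property
    def G_solv(self) -> float:
        return self.G_solv_polar + self.G_solv_nonpolar

    def __sub__(self, other: "EnergyTerms") -> "EnergyTerms":
        return EnergyTerms(
            E_internal=self.E_internal - other.E_internal,
            E_elec=self.E_elec - other.E_elec,
            E_vdw=self.E_vdw - other.E_vdw,
            G_solv_polar=self.G_solv_polar - other.G_solv_polar,
            G_solv_nonpolar=self.G_solv_nonpolar - other.G_solv_nonpolar,
            tag=self.tag, frame=self.frame,
        )


@dataclass
class EntropyTerms:
    """Entropy components, kcal/mol/K, at temperature T (K)."""

    S_trans: float
    S_rot: float
    S_vib: float
    temperature: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def total(self) -> float:
        return self.S_trans + self.S_rot + self.S_vib


EnergyModel = Callable[[StructureModel, np.ndarray, np.ndarray], EnergyTerms]


@dataclass
class ToyEnergyModel:
    """Closed-form pairwise energy model for testing the bookkeeping.

    E_elec = sum_{i<j} k q_i q_j / (eps r_ij), k = 332.0636 kcal·Å/(mol·e²);
    E_vdW  = sum_{i<j} 4 sqrt(e_i e_j) [(s_ij/r)^12 − (s_ij/r)^6],
             s_ij = (s_i + s_j)/2 (Lorentz–Berthelot);
    G_solv = per-atom linear increments (one-body, so they cancel exactly in
             complex − parts differences).
    """

    charges: np.ndarray
    lj_epsilon: np.ndarray
    lj_sigma: np.ndarray
    solv_polar: np.ndarray
    solv_nonpolar: np.ndarray
    dielectric: float = 1.0
    coulomb_k: float = COULOMB_K

    def __call__(self, topology: StructureModel, coords: np.ndarray,
                 indices: np.ndarray) -> EnergyTerms:
        idx = np.asarray(indices, dtype=int)
        x = coords[idx]
        q = self.charges[idx]
        eps = self.lj_epsilon[idx]
        sig = self.lj_sigma[idx]
        e_elec = e_vdw = 0.0
        n = len(idx)
        if n > 1:
            diff = x[:, None, :] - x[None, :, :]
            r = np.sqrt((diff ** 2).sum(axis=-1))
            iu = np.triu_indices(n, k=1)
            rij = r[iu]
            if np.any(rij <= 0):
                raise ValueError("coincident atoms in energy evaluation")
            qq = np.outer(q, q)[iu]
            e_elec = float((self.coulomb_k * qq / (self.dielectric * rij)).sum())
            eij = np.sqrt(np.outer(eps, eps))[iu]
            sij = (0.5 * (sig[:, None] + sig[None, :]))[iu]
            sr6 = (sij / rij) ** 6
            e_vdw = float((4.0 * eij * (sr6 ** 2 - sr6)).sum())
        return EnergyTerms(
            E_internal=0.0, E_elec=e_elec, E_vdw=e_vdw,
            G_solv_polar=float(self.solv_polar[idx].sum()),
            G_solv_nonpolar=float(self.solv_nonpolar[idx].sum()),
        )


def frame_terms(traj: TrajectoryEnsemble, frame: int, subset: AtomSelection,
                model: EnergyModel, tag: str = "subset") -> EnergyTerms:
    """Energy terms of an atom subset in isolation, for one frame."""
    try:
        terms = model(traj.topology, traj.frames[frame], subset.indices)
    except Exception as exc:
        raise RuntimeError(
            f"energy model failed on frame {frame}, subset {subset.label!r}: {exc}"
        ) from exc
    terms.tag = tag
    terms.frame = frame
    return terms


def interaction_terms(traj: TrajectoryEnsemble, frame: int,
                      receptor: AtomSelection, ligand: AtomSelection,
                      model: EnergyModel) -> EnergyTerms:
    """Complex − receptor − ligand term differences on one frame."""
    r = set(receptor.indices.tolist())
    l = set(ligand.indices.tolist())
    if r & l:
        raise ValueError("receptor and ligand selections overlap")
    both = AtomSelection(indices=np.array(sorted(r | l)), label="complex")
    t_c = frame_terms(traj, frame, both, model, tag="complex")
    t_r = frame_terms(traj, frame, receptor, model, tag="receptor")
    t_l = frame_terms(traj, frame, ligand, model, tag="ligand")
    out = t_c - t_r - t_l
    out.tag = "interaction"
    return out


def quasiharmonic_entropy(traj: TrajectoryEnsemble, selection: AtomSelection,
                          temperature: float = 310.0, window: slice | None = None,
                          n_skip: int = 6, masses: np.ndarray | None = None) -> float:
    """Quasi-harmonic vibrational entropy (kcal/mol/K) of a selection.

    Eigenvalues λ_k of the mass-weighted coordinate covariance define
    quasi-harmonic frequencies ω_k = sqrt(k_B T / λ_k); each mode
    contributes the quantum harmonic-oscillator entropy

        S_k = k_B [ x/(e^x − 1) − ln(1 − e^{−x}) ],  x = ħω_k / k_B T.

    The ``n_skip`` lowest-frequency (largest-λ) modes are discarded as
    rigid-body motion; modes with negligible variance contribute nothing
    (their frequency diverges), so a frozen ensemble has S_vib = 0.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    frames = traj.frames if window is None else traj.frames[window]
    if frames.shape[0] < 2:
        raise ValueError("quasi-harmonic entropy needs at least 2 frames")
    idx = selection.indices
    if masses is None:
        masses = atom_masses(traj.topology, idx)
    x = frames[:, idx].reshape(frames.shape[0], -1)          # (F, 3N)
    xc = x - x.mean(axis=0)
    w = np.repeat(np.sqrt(masses), 3)
    C = (xc * w).T @ (xc * w) / x.shape[0]                   # amu·Å²
    lam = np.linalg.eigvalsh(C)
    lam = np.sort(lam)[::-1]                                 # descending λ = ascending ω
    lam = lam[max(0, n_skip):]
    kT = const.k * temperature                               # J
    s = 0.0
    for l in lam:
        if l <= 1e-10:
            continue                                         # ω → ∞, S → 0
        omega = np.sqrt(kT / (l * _AMU * 1e-20))             # rad/s
        xk = const.hbar * omega / kT
        s += xk / np.expm1(xk) - np.log1p(-np.exp(-xk))
    return KB_KCAL * s


def rigid_body_entropy(structure: StructureModel, subset: AtomSelection,
                       temperature: float = 310.0,
                       pressure: float = _ATM) -> tuple[float, float]:
    """Translational (Sackur–Tetrode) and rigid-rotor rotational entropy.

    Returns (S_trans, S_rot) in kcal/mol/K for one molecule treated as an
    ideal gas at the given T (K) and P (Pa), symmetry number 1.  Collinear
    subsets are handled as linear rotors (two rotational degrees of
    freedom); a point-like subset has no defined rotational entropy.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    idx = subset.indices
    m = atom_masses(structure, idx)
    M = m.sum() * _AMU                                       # kg
    kT = const.k * temperature
    lam_q = (2.0 * np.pi * M * kT) / const.h ** 2            # 1/m²
    s_trans = KB_KCAL * (np.log(lam_q ** 1.5 * kT / pressure) + 2.5)

    coords = structure.coords[idx] * 1e-10                   # m
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    d = coords - com
    mk = m * _AMU
    inertia = np.zeros((3, 3))
    r2 = (d ** 2).sum(axis=1)
    for a in range(3):
        for b in range(3):
            inertia[a, b] = (mk * ((r2 if a == b else 0.0) - d[:, a] * d[:, b])).sum()
    moments = np.linalg.eigvalsh(inertia)
    if moments[-1] <= 0:
        raise ValueError("inertia tensor is degenerate (point-like subset)")
    if moments[0] <= 1e-8 * moments[-1]:
        # linear rotor (diatomic or collinear): two rotational DOF
        I_lin = 0.5 * (moments[1] + moments[2])
        s_rot = KB_KCAL * (np.log(8.0 * np.pi ** 2 * I_lin * kT / const.h ** 2) + 1.0)
    else:
        rot_arg = (np.sqrt(np.pi * np.prod(moments))
                   * (8.0 * np.pi ** 2 * kT / const.h ** 2) ** 1.5)
        s_rot = KB_KCAL * (np.log(rot_arg) + 1.5)
    return float(s_trans), float(s_rot)


@dataclass
class BindingFreeEnergy:
    """Replicate-resolved binding free energy decomposition (kcal/mol).

    The identity dG_b = <dE_MM> + <dG_sol> − T·dS holds exactly for the
    stored parts, per replicate and for the means.
    """

    dE_MM: np.ndarray              # per replicate
    dG_sol: np.ndarray
    TdS: np.ndarray
    temperature: float
    window: tuple[int, int]
    replicates: list = field(default_factory=list)

    @property
    def dG_b(self) -> np.ndarray:
        return self.dE_MM + self.dG_sol - self.TdS

    def _stats(self, x: np.ndarray) -> tuple[float, float]:
        x = np.asarray(x, dtype=float)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return float(np.mean(x)), sd

    def summary(self) -> dict:
        out = {}
        for name, arr in (("dE_MM", self.dE_MM), ("dG_sol", self.dG_sol),
                          ("minus_TdS", -self.TdS), ("dG_b", self.dG_b)):
            mean, sd = self._stats(arr)
            out[name] = {"mean": mean, "sd": sd, "per_replicate": list(map(float, arr))}
        out["temperature_K"] = self.temperature
        out["frame_window"] = list(self.window)
        return out


def binding_free_energy(
    trajectories: TrajectoryEnsemble | Sequence[TrajectoryEnsemble],
    receptor: AtomSelection,
    ligand: AtomSelection,
    model: EnergyModel,
    temperature: float = 310.0,
    window: slice | None = None,
    include_entropy: bool = True,
    pressure: float = _ATM,
    n_skip_modes: int = 6,
) -> BindingFreeEnergy:
    """Ensemble-averaged binding free energy over one or more replicates.

    Single-trajectory protocol: receptor and ligand terms are evaluated on
    the complex's own frames, so internal (bonded) contributions cancel
    identically.  ``window`` defaults to the final half of each trajectory
    (equilibration discard); entropy uses the same window.
    """
    if isinstance(trajectories, TrajectoryEnsemble):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("need at least one trajectory")
    r = set(receptor.indices.tolist())
    l = set(ligand.indices.tolist())
    if r & l:
        raise ValueError("receptor and ligand selections overlap")
    both = AtomSelection(indices=np.array(sorted(r | l)), label="complex")

    de_mm, dg_sol, tds, reps = [], [], [], []
    win_used = (0, 0)
    for traj in trajectories:
        F = traj.n_frames
        win = window if window is not None else slice(F // 2, F)
        frames_idx = range(*win.indices(F))
        if len(frames_idx) == 0:
            raise ValueError("frame window is empty")
        win_used = (frames_idx[0], frames_idx[-1] + 1)
        terms = [interaction_terms(traj, f, receptor, ligand, model) for f in frames_idx]
        de_mm.append(float(np.mean([t.E_MM for t in terms])))
        dg_sol.append(float(np.mean([t.G_solv for t in terms])))
        if include_entropy:
            from .fluctuations import mean_structure

            mean_top = traj.topology.with_coords(mean_structure(
                TrajectoryEnsemble(topology=traj.topology, frames=traj.frames[win],
                                   replicate=traj.replicate)))
            ds_total = 0.0
            for sign, sel in ((+1, both), (-1, receptor), (-1, ligand)):
                s_tr, s_rot = rigid_body_entropy(mean_top, sel, temperature, pressure)
                s_vib = quasiharmonic_entropy(traj, sel, temperature, win, n_skip_modes)
                ds_total += sign * (s_tr + s_rot + s_vib)
            tds.append(temperature * ds_total)
        else:
            tds.append(0.0)
        reps.append(traj.replicate)
    return BindingFreeEnergy(dE_MM=np.array(de_mm), dG_sol=np.array(dg_sol),
                             TdS=np.array(tds), temperature=temperature,
                             window=win_used, replicates=reps)
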