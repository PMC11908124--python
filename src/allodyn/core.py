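"""Domain types and structure/trajectory I/O.

Coordinates are Å everywhere; no unit conversion happens inside readers.
Residues carry two identities: a dense 0-based internal index used by all
matrices and graphs, and the (chain id, author residue number) pair used at
I/O boundaries. :class:`ResidueMap` is the bridge between the two.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "StructureModel",
    "TrajectoryEnsemble",
    "AtomSelection",
    "ResidueMap",
    "ParseError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_trajectory_pdb",
    "select",
    "write_matrix_tsv",
]

AMINO_ACIDS_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common variants
    "HSD": "H", "HSE": "H", "HSP": "H", "MSE": "M",
}


class ParseError(ValueError):
    """A structure or trajectory file could not be parsed."""


class SelectionError(ValueError):
    """An atom selection predicate matched nothing or is malformed."""


@dataclass
class StructureModel:
    """A molecular topology with one set of coordinates.

    Atom-level arrays all have length ``n_atoms``; atom indices are the
    implicit positions 0..n_atoms-1.  ``residue_index`` maps every atom to a
    dense 0-based residue index; the residue tables (``res_chain_id``,
    ``res_number``, ``res_names``) are indexed by that residue index.
    """

    atom_name: np.ndarray          # (A,) str
    element: np.ndarray            # (A,) str
    chain_id: np.ndarray           # (A,) str
    res_number: np.ndarray         # (A,) int, author numbering
    res_name: np.ndarray           # (A,) str
    hetero: np.ndarray             # (A,) bool
    coords: np.ndarray             # (A, 3) float, Å
    residue_index: np.ndarray = field(default=None)  # (A,) int, filled in __post_init__

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (A, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.residue_index is None:
            self.residue_index = self._assign_residues()

    def _assign_residues(self) -> np.ndarray:
        idx = np.empty(self.n_atoms, dtype=int)
        seen: dict[tuple, int] = {}
        current = -1
        prev_key = None
        for a in range(self.n_atoms):
            key = (str(self.chain_id[a]), int(self.res_number[a]), str(self.res_name[a]))
            if key != prev_key:
                if key in seen:
                    current = seen[key]
                else:
                    current += 1
                    seen[key] = current
                prev_key = key
            idx[a] = current
        return idx

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max()) + 1 if self.n_atoms else 0

    def residue_table(self) -> list[tuple[str, int, str]]:
        """Ordered (chain id, author number, residue name) per residue."""
        table: list[tuple[str, int, str]] = []
        seen = set()
        for a in range(self.n_atoms):
            r = int(self.residue_index[a])
            if r not in seen:
                seen.add(r)
                table.append((str(self.chain_id[a]), int(self.res_number[a]), str(self.res_name[a])))
        return table

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return StructureModel(
            atom_name=self.atom_name, element=self.element, chain_id=self.chain_id,
            res_number=self.res_number, res_name=self.res_name, hetero=self.hetero,
            coords=np.asarray(coords, dtype=float), residue_index=self.residue_index,
        )


@dataclass
class TrajectoryEnsemble:
    """An ordered ensemble of frames over a fixed topology."""

    topology: StructureModel
    frames: np.ndarray                 # (F, A, 3) float, Å
    times: np.ndarray | None = None    # (F,) arbitrary units
    replicate: int | str = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, A, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"atom count mismatch: topology has {self.topology.n_atoms} atoms, "
                f"frames have {self.frames.shape[1]}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame coordinates must be finite")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class AtomSelection:
    """Strictly increasing atom indices within a topology."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise SelectionError(f"selection {self.label!r} is empty")
        if np.any(np.diff(idx) <= 0):
            raise SelectionError("selection indices must be strictly increasing")
        if idx[0] < 0:
            raise SelectionError("selection indices must be non-negative")

    def __len__(self) -> int:
        return int(self.indices.size)


class ResidueMap:
    """Bijection between dense residue indices and author numbering.

    Built over the residues touched by a selection (or all residues); the
    internal index is the 0-based position within that ordering.
    """

    def __init__(self, structure: StructureModel, selection: AtomSelection | None = None):
        table = structure.residue_table()
        if selection is None:
            res_ids = list(range(len(table)))
        else:
            res_ids, seen = [], set()
            for a in selection.indices:
                r = int(structure.residue_index[a])
                if r not in seen:
                    seen.add(r)
                    res_ids.append(r)
        self._entries = [table[r] for r in res_ids]  # (chain, author number, resname)
        self._by_author = {(c, n): i for i, (c, n, _) in enumerate(self._entries)}
        if len(self._by_author) != len(self._entries):
            raise ValueError("duplicate (chain, residue number) pairs in selection")
        self._chains = sorted({c for c, _, _ in self._entries})

    def __len__(self) -> int:
        return len(self._entries)

    def to_author(self, internal: int) -> tuple[str, int]:
        c, n, _ = self._entries[internal]
        return c, n

    def to_internal(self, chain: str, number: int) -> int:
        return self._by_author[(chain, number)]

    def label(self, internal: int) -> str:
        """Author label, e.g. ``K43`` (one chain) or ``B:K43`` (several)."""
        c, n, name = self._entries[internal]
        one = AMINO_ACIDS_3TO1.get(name, name)
        base = f"{one}{n}"
        return base if len(self._chains) == 1 else f"{c}:{base}"

    def labels(self) -> list[str]:
        return [self.label(i) for i in range(len(self))]

    def from_label(self, label: str) -> int:
        """Inverse of :meth:`label` (also accepts a bare residue number)."""
        for i in range(len(self)):
            if self.label(i) == label:
                return i
        # fall back: chain-qualified or bare author number
        text = label
        chain = None
        if ":" in text:
            chain, text = text.split(":", 1)
        digits = "".join(ch for ch in text if ch.isdigit() or ch == "-")
        if digits:
            num = int(digits)
            for i, (c, n, _) in enumerate(self._entries):
                if n == num and (chain is None or c == chain):
                    return i
        raise KeyError(f"no residue matching label {label!r}")


# ---------------------------------------------------------------------------
# Readers / writers (biotite for PDB, MDAnalysis for DCD/XTC)
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"{path}: line {lineno}: truncated {rec} record")
            if line[26] != " ":
                raise ParseError(
                    f"{path}: line {lineno}: insertion codes are not supported"
                )


def _structure_from_atom_array(arr) -> StructureModel:
    return StructureModel(
        atom_name=np.asarray(arr.atom_name, dtype=object),
        element=np.asarray(arr.element, dtype=object),
        chain_id=np.asarray(arr.chain_id, dtype=object),
        res_number=np.asarray(arr.res_id, dtype=int),
        res_name=np.asarray(arr.res_name, dtype=object),
        hetero=np.asarray(arr.hetero, dtype=bool),
        coords=np.asarray(arr.coord, dtype=float),
    )


def read_structure(path: str | Path, format: str = "pdb") -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    ATOM and HETATM records are retained; alternate locations are resolved
    to the highest-occupancy conformer.
    """
    import biotite.structure.io.pdb as pdbio

    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    try:
        pdb = pdbio.PDBFile.read(str(path))
        arr = pdbio.get_structure(pdb, model=1, altloc="occupancy")
    except ParseError:
        raise
    except Exception as exc:  # biotite raises various error types
        raise ParseError(f"{path}: failed to parse PDB: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(f"{path}: PDB file contains no atoms")
    return _structure_from_atom_array(arr)


def read_trajectory(
    topology: StructureModel,
    path: str | Path,
    format: str | None = None,
    replicate: int | str = 0,
) -> TrajectoryEnsemble:
    """Read a coordinate trajectory (multi-model PDB, DCD, or XTC)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        import biotite.structure.io.pdb as pdbio

        _validate_pdb_lines(path)
        try:
            pdb = pdbio.PDBFile.read(str(path))
            stack = pdbio.get_structure(pdb, altloc="occupancy")
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"{path}: failed to parse multi-model PDB: {exc}") from exc
        frames = np.asarray(stack.coord, dtype=float)
        if frames.ndim == 2:  # single model
            frames = frames[None]
    elif fmt in ("dcd", "xtc"):
        import warnings

        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(topology.n_atoms, trajectory=True)
            try:
                u.load_new(str(path))
            except Exception as exc:
                raise ParseError(f"{path}: failed to read {fmt.upper()}: {exc}") from exc
            frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    if frames.shape[0] == 0:
        raise ParseError(f"{path}: trajectory contains zero frames")
    if frames.shape[1] != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: topology has {topology.n_atoms} atoms, "
            f"trajectory frames have {frames.shape[1]}"
        )
    return TrajectoryEnsemble(topology=topology, frames=frames, replicate=replicate)


def write_trajectory_pdb(traj: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    top = traj.topology
    n = top.n_atoms
    arrays = []
    for f in range(traj.n_frames):
        arr = struc.AtomArray(n)
        arr.coord = traj.frames[f].astype(np.float32)
        arr.chain_id = np.asarray(top.chain_id, dtype="U4")
        arr.res_id = np.asarray(top.res_number, dtype=int)
        arr.res_name = np.asarray(top.res_name, dtype="U5")
        arr.atom_name = np.asarray(top.atom_name, dtype="U6")
        arr.element = np.asarray(top.element, dtype="U2")
        arr.hetero = np.asarray(top.hetero, dtype=bool)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = pdbio.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select(structure: StructureModel, predicate: str) -> AtomSelection:
    """Select atoms by a simple predicate string.

    Tokens (whitespace-separated, combined with AND):

    - ``calpha`` — atoms named CA in amino-acid (non-hetero) residues
    - ``chain=X`` — atoms in chain X
    - ``resid=A-B`` (or ``resid=N``) — author residue number range
    - ``all`` — every atom

    Raises :class:`SelectionError` if the result is empty.
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    tokens = predicate.split()
    if not tokens:
        raise SelectionError("empty predicate")
    for tok in tokens:
        if tok == "all":
            continue
        elif tok == "calpha":
            is_aa = np.array(
                [str(r) in AMINO_ACIDS_3TO1 for r in structure.res_name], dtype=bool
            )
            mask &= (np.asarray(structure.atom_name) == "CA") & is_aa & ~structure.hetero
        elif tok.startswith("chain="):
            mask &= np.asarray(structure.chain_id) == tok[len("chain="):]
        elif tok.startswith("resid="):
            spec = tok[len("resid="):]
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", spec)
            if m is None:
                raise SelectionError(f"malformed residue range {spec!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            mask &= (structure.res_number >= lo) & (structure.res_number <= hi)
        else:
            raise SelectionError(f"unknown selection token {tok!r}")
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise SelectionError(f"selection {predicate!r} matched no atoms")
    return AtomSelection(indices=idx, label=predicate)


# ---------------------------------------------------------------------------
# Matrix TSV export
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    """Write a square matrix as TSV with author residue labels."""
    import pandas as pd

    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if len(labels) != matrix.shape[0]:
        raise ValueError("label count must match matrix dimension")
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.10g")
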