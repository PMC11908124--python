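import numpy as np
import pytest

from allodyn.core import StructureModel


def pdb_line(serial, name, resname, chain, resseq, x, y, z,
             alt=" ", occ=1.0, elem="C", record="ATOM"):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record:<6s}{serial:5d} {name_field}{alt}{resname:<3s} {chain}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {elem:>2s}")


def write_pdb(path, lines):
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Minimal Cα-only chain: three residues on the x axis."""
    lines = [
        pdb_line(1, "CA", "GLY", "A", 40, 0.0, 0.0, 0.0),
        pdb_line(2, "CA", "ALA", "A", 41, 3.8, 0.0, 0.0),
        pdb_line(3, "CA", "LYS", "A", 43, 7.6, 0.0, 0.0),
    ]
    return write_pdb(tmp_path / "three.pdb", lines)


def make_structure(coords, atom_names=None, res_names=None, res_numbers=None,
                   chains=None, elements=None):
    """Hand-build a StructureModel from coordinate rows."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return StructureModel(
        atom_name=np.array(atom_names or ["CA"] * n, dtype=object),
        element=np.array(elements or ["C"] * n, dtype=object),
        chain_id=np.array(chains or ["A"] * n, dtype=object),
        res_number=np.array(res_numbers if res_numbers is not None else range(1, n + 1)),
        res_name=np.array(res_names or ["ALA"] * n, dtype=object),
        hetero=np.zeros(n, dtype=bool),
        coords=coords,
    )
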