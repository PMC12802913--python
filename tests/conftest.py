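import numpy as np
import pytest

from taildyn.trajectory import AtomRecord, Trajectory


def make_atom(atom_id, name="CA", element="C", residue_id=1, residue_name="ALA",
              chain_id="A", mass=12.011):
    return AtomRecord(atom_id, name, element, residue_id, residue_name, chain_id, mass)


@pytest.fixture
def tiny_pdb(tmp_path):
    """Hand-written 3-atom PDB (N, CA, H of one alanine)."""
    lines = [
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C",
        "ATOM      3  H   ALA A   1       1.000   2.000   4.020  1.00  0.00           H",
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tiny_pdb_no_element(tmp_path):
    """Same 3 atoms without the element column: inference must kick in."""
    lines = [
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00",
        "ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00",
        "ATOM      3  H   ALA A   1       1.000   2.000   4.020  1.00  0.00",
        "END",
    ]
    path = tmp_path / "tiny_noel.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def write_multimodel_pdb(path, coords_per_model):
    """Write an n-model PDB of the 3-atom alanine system."""
    names = [(" N  ", "N"), (" CA ", "C"), (" H  ", "H")]
    with open(path, "w") as fh:
        for m, coords in enumerate(coords_per_model, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, ((name, el), xyz) in enumerate(zip(names, coords), start=1):
                fh.write(
                    f"ATOM  {i:5d} {name} ALA A   1    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {el:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def bead_trajectory(coords, chain_ids=None, residue_ids=None, names=None,
                    elements=None, frame_interval=1.0):
    """Trajectory of single-atom bead residues from an (F, N, 3) array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    chain_ids = chain_ids or ["A"] * n
    residue_ids = residue_ids or list(range(1, n + 1))
    names = names or ["CA"] * n
    elements = elements or ["C"] * n
    atoms = [
        AtomRecord(i + 1, names[i], elements[i], residue_ids[i], "BEA", chain_ids[i],
                   1.008 if elements[i] == "H" else 12.011)
        for i in range(n)
    ]
    return Trajectory(atoms, coords, frame_interval)
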