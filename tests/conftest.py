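import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from bioisofind import (Atom, LigandInstance, ProteinComplex, Residue,
                        perceive_ligand_graph)


def hexagon_coords(bond_length: float = 1.39, z: float = 0.0) -> np.ndarray:
    ang = np.pi / 3 * np.arange(6)
    return np.column_stack([bond_length * np.cos(ang),
                            bond_length * np.sin(ang),
                            np.full(6, z)])


def make_ligand(elements, coords, het_code="LIG", bonds=(), perceive=True):
    atoms = [Atom(i + 1, f"{el.upper()}{i+1}", el, c, is_het=True)
             for i, (el, c) in enumerate(zip(elements, coords))]
    lig = LigandInstance(het_code, "A", 101, atoms, [(i, j, 1.0) for i, j in bonds])
    return perceive_ligand_graph(lig) if perceive else lig


def ligand_from_smiles(smiles, het_code="LIG", seed=7, translate=(0, 0, 0)):
    """Embed a molecule in 3D and repackage it as a perceived ligand."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i))
                       for i in range(mol.GetNumAtoms())]) + np.asarray(translate, float)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    return make_ligand(elements, coords, het_code=het_code)


@pytest.fixture
def benzene_ligand():
    return make_ligand(["C"] * 6, hexagon_coords())


@pytest.fixture
def gly_chain_pdb():
    return (
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C\n"
        "END\n"
    )


@pytest.fixture
def benzene_complex_pdb(gly_chain_pdb):
    lines = [gly_chain_pdb.replace("END\n", "").rstrip()]
    for k, (x, y, z) in enumerate(hexagon_coords(z=5.0)):
        lines.append(f"HETATM{10+k:>5d}  C{k+1}  BNZ A 101    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
    for k in range(6):
        lines.append(f"CONECT{10+k:>5d}{10+(k+1)%6:>5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def simple_complex(entry_id="REF0", residue_names=("GLY", "ALA", "SER"),
                   ligands=()):
    residues = []
    for k, name in enumerate(residue_names):
        base = np.array([3.8 * k, 0.0, 0.0])
        residues.append(Residue(name, k + 1, [
            Atom(3 * k + 1, "N", "N", base + [-1.0, 0.5, 0.0]),
            Atom(3 * k + 2, "CA", "C", base),
            Atom(3 * k + 3, "C", "C", base + [1.0, -0.5, 0.3]),
        ]))
    return ProteinComplex(entry_id, {"A": residues}, list(ligands))
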