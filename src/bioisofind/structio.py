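"""Read/write protein-ligand structures and perceive ligand chemistry.

PDB-format complexes are parsed into light-weight containers: polymer
chains of residues, plus every non-water HETATM group as a ligand
instance (metal ions included, as single-atom ligands).  Hydrogens are
dropped on input -- deposited crystal structures mostly lack them and
the whole pipeline is heavy-atom based.

Bond perception on ligands combines three sources, in order:

1. CONECT records from the file,
2. interatomic distances against covalent radii (bonded iff
   ``d <= r_i + r_j + 0.4`` angstrom),
3. geometry-based order assignment: planar 5-7 rings of C/N/O/S become
   aromatic, short non-ring bonds are promoted to double/triple bonds,
   and RDKit sanitization validates the result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio.Data.PDBData import protein_letters_3to1
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

RDLogger.DisableLog("rdApp.*")

WATER_NAMES = {"HOH", "DOD", "WAT"}

#: extra reach added to the sum of covalent radii when perceiving bonds (A)
BOND_FUDGE = 0.4
#: two atoms closer than this are a steric clash, not a bond (A)
CLASH_DISTANCE = 0.5

# upper distance bounds (A) for promoting a perceived single bond
_DOUBLE_BOND_MAX = {
    ("C", "C"): 1.43, ("C", "N"): 1.38, ("C", "O"): 1.33,
    ("N", "N"): 1.32, ("N", "O"): 1.30, ("C", "S"): 1.70,
    ("S", "O"): 1.55,
}
_TRIPLE_BOND_MAX = {("C", "C"): 1.25, ("C", "N"): 1.20, ("N", "N"): 1.15}

_METALS = {
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE",
    "CO", "NI", "CU", "ZN", "CD", "HG", "AL", "GA", "PB",
}


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input; names the offending line."""


class ClashError(ValueError):
    """Raised when two ligand atoms sit impossibly close together."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_het: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: missing element symbol")


@dataclass
class Residue:
    name: str
    number: int
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class LigandInstance:
    het_code: str
    chain_id: str
    residue_number: int
    atoms: list[Atom] = field(default_factory=list)
    #: (atom index, atom index, bond order); order 1.5 marks aromatic
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    #: sanitized RDKit molecule, populated by perceive_ligand_graph
    mol: Chem.Mol | None = None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def is_metal_ion(self) -> bool:
        return len(self.atoms) == 1 and self.atoms[0].element.upper() in _METALS

    def validate(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"ligand {self.het_code}: bond ({i},{j}) out of range")


@dataclass
class ProteinComplex:
    entry_id: str
    chains: dict[str, list[Residue]]
    ligands: list[LigandInstance] = field(default_factory=list)

    def __post_init__(self):
        if not self.chains:
            raise ValueError(f"{self.entry_id}: complex must have at least one chain")
        for cid in self.chains:
            self.chains[cid] = sorted(
                self.chains[cid], key=lambda r: (r.number, r.insertion_code)
            )

    def all_atoms(self):
        for residues in self.chains.values():
            for res in residues:
                yield from res.atoms
        for lig in self.ligands:
            yield from lig.atoms

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinComplex":
        """Deep copy with ``x -> R x + t`` applied to every atom."""
        def move(atom: Atom) -> Atom:
            return replace(atom, coords=rotation @ atom.coords + translation)

        chains = {
            cid: [Residue(r.name, r.number, [move(a) for a in r.atoms], r.insertion_code)
                  for r in residues]
            for cid, residues in self.chains.items()
        }
        ligands = [
            LigandInstance(l.het_code, l.chain_id, l.residue_number,
                           [move(a) for a in l.atoms], list(l.bonds), l.mol)
            for l in self.ligands
        ]
        return ProteinComplex(self.entry_id, chains, ligands)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _validate_coordinate_lines(text: str) -> None:
    n_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n_records += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: coordinate record shorter than 54 columns")
        try:
            int(line[6:11])
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed fixed-column field ({exc})") from exc
    if n_records == 0:
        raise PDBParseError("no ATOM or HETATM records in input")


def _pick_altloc(atoms: list[Atom]) -> list[Atom]:
    """One conformer per atom name: highest occupancy, ties broken toward 'A'."""
    chosen: dict[str, Atom] = {}
    for a in atoms:
        prev = chosen.get(a.name)
        if prev is None:
            chosen[a.name] = a
        elif (a.occupancy, -ord(a.altloc or "~")) > (prev.occupancy, -ord(prev.altloc or "~")):
            chosen[a.name] = a
    return list(chosen.values())


def parse_structure(text: str, entry_id: str = "XXXX") -> ProteinComplex:
    """Parse PDB-format text into a :class:`ProteinComplex`.

    First model only; hydrogens and waters discarded; one altloc kept per
    atom (highest occupancy, ties toward 'A'); CONECT records become
    ligand bonds.  Raises :class:`PDBParseError` with the line number for
    malformed coordinate records.
    """
    _validate_coordinate_lines(text)
    structure = gemmi.read_pdb_string(text)
    model = structure[0]

    serial_to_lig: dict[int, tuple[LigandInstance, int]] = {}
    chains: dict[str, list[Residue]] = {}
    ligands: list[LigandInstance] = []

    for chain in model:
        for res in chain:
            atoms = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    altloc=at.altloc if at.altloc != "\x00" else "",
                    is_het=res.het_flag == "H",
                ))
            atoms = _pick_altloc(atoms)
            if not atoms:
                continue
            names = {a.name for a in atoms}
            is_polymer = res.het_flag != "H" or {"N", "CA", "C"} <= names
            if not is_polymer:
                if res.name in WATER_NAMES:
                    continue
                lig = LigandInstance(res.name, chain.name, res.seqid.num, atoms)
                for idx, a in enumerate(atoms):
                    serial_to_lig[a.serial] = (lig, idx)
                ligands.append(lig)
            else:
                chains.setdefault(chain.name, []).append(
                    Residue(res.name, res.seqid.num, atoms, res.seqid.icode.strip())
                )

    if not chains:
        # ligand-only file: keep a placeholder empty chain is disallowed by the
        # invariant, so surface a clear error instead
        raise PDBParseError("input contains no polymer chain")

    for line in text.splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[i:i + 5].strip() for i in range(6, min(len(line), 31), 5)]
        serials = [int(f) for f in fields if f]
        if len(serials) < 2 or serials[0] not in serial_to_lig:
            continue
        lig, i = serial_to_lig[serials[0]]
        for s in serials[1:]:
            hit = serial_to_lig.get(s)
            if hit is None or hit[0] is not lig:
                continue
            j = hit[1]
            pair = (min(i, j), max(i, j))
            if pair[0] != pair[1] and not any(b[:2] == pair for b in lig.bonds):
                lig.bonds.append((pair[0], pair[1], 1.0))

    complex_ = ProteinComplex(entry_id, chains, ligands)
    for lig in ligands:
        lig.validate()
    return complex_


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _coordinate_record(kind: str, serial: int, atom: Atom, resname: str,
                       chain_id: str, resnum: int) -> str:
    x, y, z = atom.coords
    return (f"{kind:<6s}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
            f"{atom.altloc or ' '}{resname:>3s} {chain_id}{resnum:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}")


def write_structure(complex_: ProteinComplex) -> str:
    """Serialize to PDB text (ATOM/TER/HETATM/CONECT/END)."""
    lines: list[str] = []
    serial = 0
    ligand_serials: list[list[int]] = []
    for cid, residues in complex_.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_coordinate_record("ATOM", serial, atom, res.name, cid, res.number))
        serial += 1
        lines.append(f"TER   {serial:>5d}      {residues[-1].name:>3s} "
                     f"{cid}{residues[-1].number:>4d}")
    for lig in complex_.ligands:
        serials = []
        for atom in lig.atoms:
            serial += 1
            serials.append(serial)
            lines.append(_coordinate_record("HETATM", serial, atom, lig.het_code,
                                            lig.chain_id, lig.residue_number))
        ligand_serials.append(serials)
    for lig, serials in zip(complex_.ligands, ligand_serials):
        neighbours: dict[int, list[int]] = {}
        for i, j, _ in lig.bonds:
            neighbours.setdefault(i, []).append(j)
            neighbours.setdefault(j, []).append(i)
        for i in sorted(neighbours):
            partners = "".join(f"{serials[j]:>5d}" for j in sorted(neighbours[i]))
            lines.append(f"CONECT{serials[i]:>5d}{partners}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def extract_sequence(complex_: ProteinComplex, chain_id: str) -> str:
    """One-letter sequence of a chain; nonstandard residues map to 'X'."""
    if chain_id not in complex_.chains:
        raise KeyError(f"{complex_.entry_id}: no chain {chain_id!r}")
    return "".join(
        protein_letters_3to1.get(res.name, "X")
        for res in complex_.chains[chain_id]
    )


def write_fasta(records: dict[str, str]) -> str:
    out = []
    for header, seq in records.items():
        out.append(f">{header}")
        out.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# ligand chemistry perception
# ---------------------------------------------------------------------------

def covalent_radius(element: str) -> float:
    return gemmi.Element(element).covalent_r


def _distance_bonds(atoms: list[Atom]) -> set[tuple[int, int]]:
    coords = np.array([a.coords for a in atoms])
    radii = np.array([covalent_radius(a.element) for a in atoms])
    bonds = set()
    for i, j in itertools.combinations(range(len(atoms)), 2):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < CLASH_DISTANCE:
            raise ClashError(f"atoms {atoms[i].name} and {atoms[j].name} are {d:.2f} A apart")
        if d <= radii[i] + radii[j] + BOND_FUDGE:
            bonds.add((i, j))
    return bonds


def _ring_planarity(coords: np.ndarray) -> float:
    centered = coords - coords.mean(axis=0)
    return float(np.linalg.svd(centered, compute_uv=False)[-1] / np.sqrt(len(coords)))


def _build_mol(atoms: list[Atom], bonds, aromatic_atoms=frozenset(),
               aromatic_bonds=frozenset(), pyrrole_n=frozenset(),
               orders=None) -> Chem.Mol:
    rw = Chem.RWMol()
    conf = Chem.Conformer(len(atoms))
    for i, a in enumerate(atoms):
        rd = Chem.Atom(a.element.capitalize())
        if i in aromatic_atoms:
            rd.SetIsAromatic(True)
        if i in pyrrole_n:
            rd.SetNumExplicitHs(1)
        if len(atoms) == 1 and a.element.upper() in _METALS:
            rd.SetNoImplicit(True)
        rw.AddAtom(rd)
        conf.SetAtomPosition(i, Point3D(*a.coords))
    for i, j in bonds:
        if (i, j) in aromatic_bonds:
            bt = Chem.BondType.AROMATIC
        else:
            order = (orders or {}).get((i, j), 1.0)
            bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                  3.0: Chem.BondType.TRIPLE}[order]
        rw.AddBond(i, j, bt)
        if (i, j) in aromatic_bonds:
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    mol = rw.GetMol()
    mol.AddConformer(conf)
    return mol


def _try_sanitize(mol: Chem.Mol) -> Chem.Mol | None:
    try:
        Chem.SanitizeMol(mol)
        return mol
    except (Chem.AtomValenceException, Chem.KekulizeException, ValueError):
        return None


def perceive_ligand_graph(ligand: LigandInstance) -> LigandInstance:
    """Return a copy of *ligand* with a complete, sanitized chemical graph.

    Bonds are the union of CONECT bonds and covalent-radius distance
    bonds.  Planar 5-7 membered rings of C/N/O/S are perceived aromatic;
    short non-ring bonds become double/triple bonds when valence allows.
    The sanitized RDKit molecule is stored on ``.mol``.
    """
    atoms = ligand.atoms
    if not atoms:
        raise ValueError("ligand has no atoms")

    bonds = {(min(i, j), max(i, j)) for i, j, _ in ligand.bonds}
    bonds |= _distance_bonds(atoms)
    bonds = sorted(bonds)

    skeleton = _build_mol(atoms, bonds)
    Chem.SanitizeMol(skeleton, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                     | Chem.SanitizeFlags.SANITIZE_SYMMRINGS)

    coords = np.array([a.coords for a in atoms])
    aromatic_atoms: set[int] = set()
    aromatic_bonds: set[tuple[int, int]] = set()
    degree = {i: 0 for i in range(len(atoms))}
    for i, j in bonds:
        degree[i] += 1
        degree[j] += 1
    for ring in Chem.GetSymmSSSR(skeleton):
        ring = list(ring)
        if not 5 <= len(ring) <= 7:
            continue
        if any(atoms[i].element not in {"C", "N", "O", "S"} for i in ring):
            continue
        if any(degree[i] > 3 for i in ring):
            continue
        if _ring_planarity(coords[ring]) > 0.1:
            continue
        aromatic_atoms.update(ring)
        for a, b in zip(ring, ring[1:] + ring[:1]):
            aromatic_bonds.add((min(a, b), max(a, b)))

    mol = None
    if aromatic_atoms:
        mol = _try_sanitize(_build_mol(atoms, bonds, aromatic_atoms, aromatic_bonds))
        if mol is None:
            # pyrrole/imidazole-type NH needed for an aromatic sextet
            nh = {i for i in aromatic_atoms
                  if atoms[i].element == "N" and degree[i] == 2}
            mol = _try_sanitize(_build_mol(atoms, bonds, aromatic_atoms,
                                           aromatic_bonds, pyrrole_n=nh))
        if mol is None:
            aromatic_atoms, aromatic_bonds = set(), set()

    if mol is None:
        # promote short bonds, shortest first, respecting valence
        pt = Chem.GetPeriodicTable()
        used = {i: float(degree[i]) for i in range(len(atoms))}
        orders: dict[tuple[int, int], float] = {}
        lengths = {(i, j): float(np.linalg.norm(coords[i] - coords[j])) for i, j in bonds}
        for (i, j) in sorted(bonds, key=lambda b: lengths[b]):
            pair = tuple(sorted((atoms[i].element, atoms[j].element)))
            d = lengths[(i, j)]
            free_i = pt.GetDefaultValence(atoms[i].element) - used[i]
            free_j = pt.GetDefaultValence(atoms[j].element) - used[j]
            if d <= _TRIPLE_BOND_MAX.get(pair, 0.0) and free_i >= 2 and free_j >= 2:
                orders[(i, j)] = 3.0
                used[i] += 2; used[j] += 2
            elif d <= _DOUBLE_BOND_MAX.get(pair, 0.0) and free_i >= 1 and free_j >= 1:
                orders[(i, j)] = 2.0
                used[i] += 1; used[j] += 1
        mol = _try_sanitize(_build_mol(atoms, bonds, orders=orders))
        if mol is None:
            mol = _build_mol(atoms, bonds)
            Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL
                             ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES)

    out_bonds = []
    for b in mol.GetBonds():
        order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
        out_bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    out = LigandInstance(ligand.het_code, ligand.chain_id, ligand.residue_number,
                         list(atoms), out_bonds, mol)
    out.validate()
    return out


def ligand_smiles(ligand: LigandInstance) -> str:
    """Canonical SMILES of a perceived ligand."""
    if ligand.mol is None:
        raise ValueError("ligand graph not perceived; call perceive_ligand_graph first")
    return Chem.MolToSmiles(ligand.mol)
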