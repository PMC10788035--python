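"""Probe-sphere capture and fragment extraction.

Every atom of the matched reference moiety becomes the centre of a probe
sphere (default radius 2.5 A).  Target-ligand atoms that fall inside any
probe -- in the superposed frame -- are captured, split into connected
components, chemically completed (cut bonds capped with wildcard
attachment atoms, remaining valence filled with implicit hydrogens) and
emitted as candidate replacement fragments with canonical SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D
from scipy.spatial.distance import cdist

from .structio import Atom, LigandInstance

#: probe-sphere radius around each reference-fragment atom (A)
DEFAULT_PROBE_RADIUS = 2.5
#: organic fragments smaller than this are discarded as noise
DEFAULT_MIN_ATOMS = 3


class FragmentChemistryError(ValueError):
    """Raised when a captured atom set cannot be completed into a molecule."""


@dataclass
class ProbeSet:
    centers: np.ndarray
    radius: float = DEFAULT_PROBE_RADIUS

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.radius <= 0:
            raise ValueError("probe radius must be positive")
        if self.centers.size == 0:
            raise ValueError("probe set needs at least one center")


@dataclass(frozen=True)
class Provenance:
    reference_entry: str
    reference_het: str
    target_entry: str
    target_het: str


@dataclass
class ExtractedFragment:
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    attachment_count: int
    smiles: str
    provenance: list[Provenance] = field(default_factory=list)
    fitness: "object | None" = None  # FitnessScore, set by the scoring stage
    mol: Chem.Mol | None = None
    self_replacement: bool = False

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def combined_fitness(self) -> float:
        return self.fitness.combined if self.fitness is not None else float("nan")


def capture_atoms(probes: ProbeSet, ligand: LigandInstance) -> set[int]:
    """Indices of ligand heavy atoms within *radius* of any probe center.

    Closed-ball membership: an atom exactly at the radius is captured.
    """
    coords = ligand.coords()
    if coords.size == 0:
        return set()
    dmin = cdist(coords, probes.centers).min(axis=1)
    return set(np.nonzero(dmin <= probes.radius)[0].tolist())


def _fragment_mol(ligand: LigandInstance, members: list[int],
                  cut_neighbors: list[tuple[int, int]],
                  drop_aromatic: bool = False) -> Chem.Mol:
    """Build an RDKit molecule for a captured component.

    *cut_neighbors* lists (kept atom, lost neighbour) pairs; each becomes
    a wildcard cap placed at the lost neighbour's coordinates.
    """
    src = ligand.mol
    index = {orig: k for k, orig in enumerate(members)}
    rw = Chem.RWMol()
    positions: list[np.ndarray] = []
    for orig in members:
        sa = src.GetAtomWithIdx(orig)
        a = Chem.Atom(sa.GetAtomicNum())
        a.SetFormalCharge(sa.GetFormalCharge())
        a.SetNumExplicitHs(sa.GetNumExplicitHs())
        if sa.GetIsAromatic() and not drop_aromatic:
            a.SetIsAromatic(True)
        a.SetNoImplicit(sa.GetNoImplicit())
        rw.AddAtom(a)
        positions.append(ligand.atoms[orig].coords)
    member_set = set(members)
    for b in src.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in member_set and j in member_set:
            bt = b.GetBondType()
            if drop_aromatic and bt == Chem.BondType.AROMATIC:
                bt = Chem.BondType.SINGLE
            rw.AddBond(index[i], index[j], bt)
            if b.GetIsAromatic() and not drop_aromatic:
                rw.GetBondBetweenAtoms(index[i], index[j]).SetIsAromatic(True)
    for kept, lost in cut_neighbors:
        w = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(index[kept], w, Chem.BondType.SINGLE)
        positions.append(ligand.atoms[lost].coords)
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for k, p in enumerate(positions):
        conf.SetAtomPosition(k, Point3D(*map(float, p)))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    return mol


def build_fragment(ligand: LigandInstance, members: list[int],
                   provenance: Provenance,
                   cut_neighbors: list[tuple[int, int]] | None = None) -> ExtractedFragment:
    """Complete a set of ligand atoms into an :class:`ExtractedFragment`."""
    if cut_neighbors is None:
        member_set = set(members)
        cut_neighbors = []
        for i, j, _ in ligand.bonds:
            if i in member_set and j not in member_set:
                cut_neighbors.append((i, j))
            elif j in member_set and i not in member_set:
                cut_neighbors.append((j, i))
    try:
        mol = _fragment_mol(ligand, members, cut_neighbors)
    except (Chem.AtomValenceException, Chem.KekulizeException, ValueError):
        # partial aromatic rings cannot keep their flags; retry kekulized-out
        try:
            mol = _fragment_mol(ligand, members, cut_neighbors, drop_aromatic=True)
        except (Chem.AtomValenceException, Chem.KekulizeException, ValueError) as exc:
            raise FragmentChemistryError(
                f"{provenance}: cannot complete fragment of {len(members)} atoms: {exc}"
            ) from exc
    index = {orig: k for k, orig in enumerate(members)}
    member_set = set(members)
    bonds = [(index[i], index[j], order) for i, j, order in ligand.bonds
             if i in member_set and j in member_set]
    atoms = [ligand.atoms[i] for i in members]
    return ExtractedFragment(
        atoms=atoms,
        bonds=bonds,
        attachment_count=len(cut_neighbors),
        smiles=Chem.MolToSmiles(mol),
        provenance=[provenance],
        mol=mol,
    )


def induce_fragments(ligand: LigandInstance, captured: set[int],
                     provenance: Provenance,
                     min_atoms: int = DEFAULT_MIN_ATOMS) -> list[ExtractedFragment]:
    """Split captured atoms into connected components and complete each.

    Components below *min_atoms* heavy atoms are discarded as noise,
    except single metal ions, which the binding site may genuinely reuse.
    """
    if not captured <= set(range(len(ligand.atoms))):
        raise ValueError("captured indices outside ligand")
    adjacency: dict[int, set[int]] = {i: set() for i in captured}
    for i, j, _ in ligand.bonds:
        if i in captured and j in captured:
            adjacency[i].add(j)
            adjacency[j].add(i)
    seen: set[int] = set()
    fragments = []
    for start in sorted(captured):
        if start in seen:
            continue
        component = []
        stack = [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            component.append(node)
            for nb in adjacency[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        component.sort()
        is_ion = len(component) == 1 and ligand.is_metal_ion()
        if len(component) < min_atoms and not is_ion:
            continue
        fragments.append(build_fragment(ligand, component, provenance))
    return fragments


def fragment_to_smiles(fragment: ExtractedFragment) -> str:
    """Canonical SMILES of a completed fragment (wildcards = attachments)."""
    if fragment.mol is None:
        raise FragmentChemistryError("fragment has no completed molecule")
    return Chem.MolToSmiles(fragment.mol)


def deduplicate(fragments: list[ExtractedFragment]) -> list[ExtractedFragment]:
    """One representative per canonical SMILES, keeping the best fitness.

    Provenances of all merged duplicates are retained on the survivor.
    """
    by_smiles: dict[str, ExtractedFragment] = {}
    for frag in fragments:
        cur = by_smiles.get(frag.smiles)
        if cur is None:
            by_smiles[frag.smiles] = ExtractedFragment(
                frag.atoms, frag.bonds, frag.attachment_count, frag.smiles,
                list(frag.provenance), frag.fitness, frag.mol, frag.self_replacement)
        else:
            for p in frag.provenance:
                if p not in cur.provenance:
                    cur.provenance.append(p)
            f_new = frag.fitness.combined if frag.fitness is not None else -1.0
            f_cur = cur.fitness.combined if cur.fitness is not None else -1.0
            if f_new > f_cur:
                cur.atoms, cur.bonds = frag.atoms, frag.bonds
                cur.attachment_count = frag.attachment_count
                cur.fitness, cur.mol = frag.fitness, frag.mol
                cur.self_replacement = frag.self_replacement
    return list(by_smiles.values())


def fragments_to_sdf(fragments: list[ExtractedFragment]) -> str:
    """3D SDF text for a fragment list, with fitness/provenance tags."""
    blocks = []
    for k, frag in enumerate(fragments):
        mol = Chem.Mol(frag.mol)
        mol.SetProp("_Name", f"fragment_{k}")
        block = Chem.MolToMolBlock(mol, kekulize=True)
        props = [f">  <smiles>\n{frag.smiles}\n"]
        if frag.fitness is not None:
            props.append(f">  <fitness>\n{frag.combined_fitness:.4f}\n")
        prov = frag.provenance[0]
        props.append(f">  <reference>\n{prov.reference_entry}:{prov.reference_het}\n")
        props.append(f">  <target>\n{prov.target_entry}:{prov.target_het}\n")
        blocks.append(block + "\n".join(props) + "\n$$$$\n")
    return "".join(blocks)
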