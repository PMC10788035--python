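"""Fragment queries, reference-ligand search and sequence homology.

A fragment query is a SMILES string in which ``[R]`` (or ``*``) marks
the attachment point -- the vertex where the moiety joins the rest of
its parent ligand.  The query core (everything except the attachment
wildcards) is matched as a subgraph against perceived ligand graphs;
complexes whose ligands contain the core become reference complexes.
Homologous target complexes are then selected by global sequence
alignment, standing in for a Blastp sweep over the PDB.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem

from .structio import LigandInstance, ProteinComplex, extract_sequence


class QueryParseError(ValueError):
    """Raised for SMILES the query parser cannot interpret."""


@dataclass
class FragmentQuery:
    smiles: str
    mol: Chem.Mol
    attachment_count: int

    @property
    def core_atom_count(self) -> int:
        return self.mol.GetNumAtoms() - self.attachment_count


@dataclass
class ReferenceHit:
    complex: ProteinComplex
    ligand: LigandInstance
    #: ligand atom indices matched to the query core, in query-core atom order
    match_atom_indices: tuple[int, ...]


@dataclass
class HomologuePair:
    reference_chain: tuple[str, str]
    target_chain: tuple[str, str]
    identity: float
    #: aligned (non-gap) columns as (reference residue number, target residue number)
    residue_map: list[tuple[int, int]] = field(default_factory=list)


def _diagnose_smiles(smiles: str) -> str:
    if smiles.count("(") != smiles.count(")"):
        return "unbalanced parentheses"
    digits = re.findall(r"(?<!%)\d", re.sub(r"\[[^]]*\]", "", smiles))
    counts: dict[str, int] = {}
    for d in digits:
        counts[d] = counts.get(d, 0) + 1
    odd = [d for d, c in counts.items() if c % 2]
    if odd:
        return f"unclosed ring bond {','.join(sorted(odd))}"
    return f"offending token near {smiles!r}"


def parse_fragment_query(smiles: str) -> FragmentQuery:
    """Parse a query SMILES; ``[R]`` and ``*`` both mark attachment points."""
    if not smiles or not smiles.strip():
        raise QueryParseError("empty query SMILES")
    normalized = smiles.replace("[R]", "*")
    mol = Chem.MolFromSmiles(normalized)
    if mol is None:
        raise QueryParseError(f"cannot parse query {smiles!r}: {_diagnose_smiles(normalized)}")
    attachments = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    for a in attachments:
        if a.GetDegree() != 1:
            raise QueryParseError(
                f"attachment marker in {smiles!r} must bond to exactly one atom")
    return FragmentQuery(normalized, mol, len(attachments))


def _matchable_query(query: FragmentQuery) -> Chem.Mol:
    params = Chem.AdjustQueryParameters.NoAdjustments()
    params.makeDummiesQueries = True  # '*' matches any heavy atom
    return Chem.AdjustQueryProperties(query.mol, params)


def match_substructure(ligand: LigandInstance,
                       query: FragmentQuery) -> list[tuple[int, ...]]:
    """All distinct matches of the query core in a perceived ligand.

    Attachment wildcards must map to some heavy atom (so a bare core
    without the required substituent does not match), but the wildcard
    atoms are excluded from the returned index tuples.  Matches covering
    the same ligand-atom set (ring symmetry images) are collapsed.
    """
    if ligand.mol is None:
        raise ValueError("ligand graph not perceived")
    qmol = _matchable_query(query)
    core_positions = [a.GetIdx() for a in query.mol.GetAtoms() if a.GetAtomicNum() != 0]
    seen: set[frozenset[int]] = set()
    out: list[tuple[int, ...]] = []
    for match in ligand.mol.GetSubstructMatches(qmol, uniquify=True, maxMatches=4096):
        core = tuple(match[i] for i in core_positions)
        key = frozenset(core)
        if key not in seen:
            seen.add(key)
            out.append(core)
    return out


def find_reference_hits(corpus: list[ProteinComplex],
                        query: FragmentQuery) -> list[ReferenceHit]:
    """Scan perceived ligands of every complex for the query core."""
    hits = []
    for complex_ in corpus:
        for ligand in complex_.ligands:
            if ligand.mol is None:
                continue
            for core in match_substructure(ligand, query):
                hits.append(ReferenceHit(complex_, ligand, core))
    return hits


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def align_pair(seq_a: str, seq_b: str) -> tuple[float, list[tuple[int, int]]]:
    """Global affine-gap alignment (BLOSUM62, open 11 / extend 1).

    Returns percent identity over aligned (non-gap) columns and the list
    of aligned 0-based position pairs, strictly increasing in both
    coordinates.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    identical = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if seq_a[i] == seq_b[j]:
                identical += 1
    if not pairs:
        return 0.0, []
    return 100.0 * identical / len(pairs), pairs


def select_homologues(reference: ReferenceHit, corpus: list[ProteinComplex],
                      min_identity: float = 90.0,
                      min_aligned: int = 50) -> list[HomologuePair]:
    """Best-chain homologue pairs between the reference and each target.

    Every reference chain is aligned against every chain of every other
    complex; per target complex the single best-identity chain pair at or
    above *min_identity* (with at least *min_aligned* aligned residues)
    is kept.  The reference complex never targets itself.
    """
    ref = reference.complex
    ref_seqs = {cid: extract_sequence(ref, cid) for cid in ref.chains}
    out: list[HomologuePair] = []
    for target in corpus:
        if target.entry_id == ref.entry_id:
            continue
        best: HomologuePair | None = None
        for ref_cid, ref_seq in ref_seqs.items():
            if not ref_seq:
                continue
            for tgt_cid in target.chains:
                tgt_seq = extract_sequence(target, tgt_cid)
                if not tgt_seq:
                    continue
                identity, pairs = align_pair(ref_seq, tgt_seq)
                if identity < min_identity or len(pairs) < min_aligned:
                    continue
                if best is None or identity > best.identity:
                    ref_nums = [r.number for r in ref.chains[ref_cid]]
                    tgt_nums = [r.number for r in target.chains[tgt_cid]]
                    best = HomologuePair(
                        (ref.entry_id, ref_cid), (target.entry_id, tgt_cid),
                        identity,
                        [(ref_nums[i], tgt_nums[j]) for i, j in pairs],
                    )
        if best is not None:
            out.append(best)
    return out
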