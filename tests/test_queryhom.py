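import itertools

import networkx as nx
import numpy as np
import pytest
from Bio.Align import substitution_matrices

from bioisofind import (QueryParseError, ReferenceHit, align_pair,
                        match_substructure, parse_fragment_query,
                        select_homologues)

from conftest import ligand_from_smiles, simple_complex

CATECHOL_QUERY = "Oc1cccc([R])c1O"


class TestParseQuery:
    def test_catechol_query(self):
        q = parse_fragment_query(CATECHOL_QUERY)
        assert q.core_atom_count == 8
        assert q.attachment_count == 1

    def test_single_atom_no_attachment(self):
        q = parse_fragment_query("O")
        assert q.core_atom_count == 1
        assert q.attachment_count == 0

    def test_star_and_r_are_equivalent(self):
        a = parse_fragment_query("Oc1cccc(*)c1O")
        b = parse_fragment_query(CATECHOL_QUERY)
        assert (a.core_atom_count, a.attachment_count) == \
               (b.core_atom_count, b.attachment_count)

    @pytest.mark.parametrize("bad", ["Oc1cccc(", "", "c1ccc", "C(("])
    def test_malformed_query_rejected(self, bad):
        with pytest.raises(QueryParseError):
            parse_fragment_query(bad)


def _ligand_graph(ligand):
    g = nx.Graph()
    for i, atom in enumerate(ligand.atoms):
        g.add_node(i, element=atom.element)
    for i, j, _ in ligand.bonds:
        g.add_edge(i, j)
    return g


def brute_force_core_matches(ligand, query):
    """Exhaustive subgraph-isomorphism enumeration on small graphs.

    Wildcards must map to some heavy atom; returns the set of distinct
    core atom-index sets.
    """
    g = _ligand_graph(ligand)
    q = nx.Graph()
    wild = set()
    for atom in query.mol.GetAtoms():
        q.add_node(atom.GetIdx(), element=atom.GetSymbol())
        if atom.GetAtomicNum() == 0:
            wild.add(atom.GetIdx())
    for bond in query.mol.GetBonds():
        q.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, q,
        node_match=lambda a, b: b["element"] == "*" or a["element"] == b["element"])
    found = set()
    for mapping in matcher.subgraph_monomorphisms_iter():
        inv = {qi: gi for gi, qi in mapping.items()}
        found.add(frozenset(inv[qi] for qi in q.nodes if qi not in wild))
    return found


class TestMatchSubstructure:
    def test_methylcatechol_matches_once(self):
        lig = ligand_from_smiles("Cc1cccc(O)c1O")
        query = parse_fragment_query(CATECHOL_QUERY)
        matches = match_substructure(lig, query)
        assert len(matches) == 1
        assert {frozenset(m) for m in matches} == brute_force_core_matches(lig, query)

    def test_benzene_has_no_oxygens(self):
        lig = ligand_from_smiles("c1ccccc1")
        assert match_substructure(lig, parse_fragment_query(CATECHOL_QUERY)) == []

    def test_bare_catechol_lacks_attachment_atom(self):
        lig = ligand_from_smiles("Oc1ccccc1O")
        query = parse_fragment_query(CATECHOL_QUERY)
        assert match_substructure(lig, query) == []
        assert brute_force_core_matches(lig, query) == set()

    def test_match_count_invariant_under_atom_order(self):
        lig = ligand_from_smiles("Cc1cccc(O)c1O")
        query = parse_fragment_query(CATECHOL_QUERY)
        n_ref = len(match_substructure(lig, query))
        rng = np.random.default_rng(0)
        for _ in range(3):
            order = rng.permutation(len(lig.atoms))
            from conftest import make_ligand
            shuffled = make_ligand([lig.atoms[i].element for i in order],
                                   [lig.atoms[i].coords for i in order])
            assert len(match_substructure(shuffled, query)) == n_ref


def brute_force_align(seq_a, seq_b):
    """Enumerate all monotone residue matchings with affine gap scoring."""
    blosum = substitution_matrices.load("BLOSUM62")

    def gap_cost(length):
        return 0.0 if length == 0 else -11.0 - (length - 1) * 1.0

    best_score, best_maps = -np.inf, []
    positions_a = range(len(seq_a))
    for k in range(min(len(seq_a), len(seq_b)) + 1):
        for sub_a in itertools.combinations(positions_a, k):
            for sub_b in itertools.combinations(range(len(seq_b)), k):
                score = sum(blosum[seq_a[i], seq_b[j]]
                            for i, j in zip(sub_a, sub_b))
                bounds_a = [-1, *sub_a, len(seq_a)]
                bounds_b = [-1, *sub_b, len(seq_b)]
                for s in range(k + 1):
                    score += gap_cost(bounds_a[s + 1] - bounds_a[s] - 1)
                    score += gap_cost(bounds_b[s + 1] - bounds_b[s] - 1)
                if score > best_score + 1e-9:
                    best_score, best_maps = score, [list(zip(sub_a, sub_b))]
                elif abs(score - best_score) <= 1e-9:
                    best_maps.append(list(zip(sub_a, sub_b)))

    def identity(mapping):
        if not mapping:
            return 0.0
        same = sum(seq_a[i] == seq_b[j] for i, j in mapping)
        return 100.0 * same / len(mapping)

    return best_score, best_maps, max(identity(m) for m in best_maps)


class TestAlignPair:
    def test_identical_sequences(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        identity, pairs = align_pair(seq, seq)
        assert identity == 100.0
        assert pairs == [(i, i) for i in range(20)]

    def test_single_substitution(self):
        a = "ACDEFGHIKL"
        b = "ACDEFGHIKV"
        identity, pairs = align_pair(a, b)
        assert identity == pytest.approx(90.0)
        assert len(pairs) == 10

    def test_tiny_alignment_matches_exhaustive_oracle(self):
        a, b = "ACD", "AD"
        identity, pairs = align_pair(a, b)
        _, best_maps, best_identity = brute_force_align(a, b)
        assert pairs in best_maps
        assert identity == pytest.approx(best_identity)

    def test_identity_is_symmetric(self):
        rng = np.random.default_rng(3)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(5):
            a = "".join(rng.choice(alphabet, size=12))
            b = "".join(rng.choice(alphabet, size=15))
            assert align_pair(a, b)[0] == pytest.approx(align_pair(b, a)[0])

    def test_residue_map_monotone(self):
        _, pairs = align_pair("ACDEFGHIKLMNP", "ACDFGHKLMNP")
        assert all(p1[0] < p2[0] and p1[1] < p2[1]
                   for p1, p2 in zip(pairs, pairs[1:]))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACD")


def _hit(complex_):
    lig = ligand_from_smiles("Cc1cccc(O)c1O", het_code="CAT")
    return ReferenceHit(complex_, lig, (0, 1, 2))


class TestSelectHomologues:
    def test_identical_copy_found_at_100(self):
        ref = simple_complex("REF0", ("GLY", "ALA", "SER", "TRP", "LYS"))
        copy = simple_complex("TGT1", ("GLY", "ALA", "SER", "TRP", "LYS"))
        pairs = select_homologues(_hit(ref), [ref, copy],
                                  min_identity=90, min_aligned=3)
        assert len(pairs) == 1
        assert pairs[0].identity == pytest.approx(100.0)
        assert pairs[0].target_chain == ("TGT1", "A")

    def test_reference_not_its_own_target(self):
        ref = simple_complex("REF0", ("GLY", "ALA", "SER", "TRP", "LYS"))
        assert select_homologues(_hit(ref), [ref], min_identity=50,
                                 min_aligned=3) == []

    def test_unrelated_sequence_excluded(self):
        ref = simple_complex("REF0", ("GLY", "ALA", "SER", "TRP", "LYS"))
        other = simple_complex("TGT1", ("PRO", "PRO", "HIS", "GLU", "MET"))
        assert select_homologues(_hit(ref), [ref, other], min_identity=90,
                                 min_aligned=3) == []

    def test_threshold_boundary_uses_align_pair(self):
        names = ["GLY", "ALA", "SER", "TRP", "LYS", "PHE", "TYR", "VAL",
                 "LEU", "ILE", "MET", "HIS", "GLU", "ASP", "ARG", "ASN",
                 "GLN", "THR", "CYS", "PRO"]
        ref = simple_complex("REF0", tuple(names))
        mutated = list(names)
        mutated[0] = "PRO"  # 19/20 identical -> 95%
        tgt = simple_complex("TGT1", tuple(mutated))
        ident, _ = align_pair("".join("GASWKFYVLIMHEDRNQTCP"),
                              "".join("PASWKFYVLIMHEDRNQTCP"))
        pairs = select_homologues(_hit(ref), [ref, tgt], min_identity=90,
                                  min_aligned=10)
        assert len(pairs) == 1
        assert pairs[0].identity == pytest.approx(ident)
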