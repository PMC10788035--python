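"""End-to-end orchestration and the synthetic fixture corpus.

``run_search`` chains the whole method: query parsing, reference-ligand
search, sequence homology, superposition, probe-sphere capture, fitness
scoring, deduplication, categorization and clustering.

``generate_fixture_corpus`` builds a miniature corpus of protein-ligand
complexes entirely in memory: a helical peptide chain carrying a
3-substituted-catechol-type reference ligand, plus homologous copies
(same sequence, rigid-motion + noise coordinates) whose ligands are
planted replacement fragments occupying the reference moiety's location.
It exists so the full pipeline is exercisable and testable with no
structure downloads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from . import classify_cluster as cc
from .extract import (DEFAULT_MIN_ATOMS, DEFAULT_PROBE_RADIUS, ExtractedFragment,
                      ProbeSet, Provenance, build_fragment, capture_atoms,
                      deduplicate, fragments_to_sdf, induce_fragments)
from .fitness import FitnessConfig, filter_rank, score_fragment
from .queryhom import (FragmentQuery, ReferenceHit, find_reference_hits,
                       parse_fragment_query, select_homologues)
from .structio import (Atom, LigandInstance, ProteinComplex, Residue,
                       parse_structure, perceive_ligand_graph, write_structure)
from .superpose import SuperpositionError, superpose_by_mapping

logger = logging.getLogger(__name__)

_AA3 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"]


@dataclass
class SearchConfig:
    probe_radius: float = DEFAULT_PROBE_RADIUS
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    min_identity: float = 90.0
    min_aligned: int = 50
    min_atoms: int = DEFAULT_MIN_ATOMS
    fingerprint: cc.FingerprintConfig = field(default_factory=cc.FingerprintConfig)
    cluster_algorithm: str = "kmeans"
    max_clusters: int = 10
    embed_dims: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity is a percentage")


@dataclass
class FixtureSpec:
    """Conditions of the synthetic corpus.

    Defaults: a 60-residue chain (long enough for the homology filter's
    aligned-length floor), a 3-methylcatechol reference ligand, one
    planted pyridine replacement per homologue, and 0.1 A coordinate
    noise -- about the coordinate uncertainty of close crystallographic
    homologues.
    """
    n_complexes: int = 4
    planted_smiles: tuple[str, ...] = ("c1ccncc1",)
    reference_ligand_smiles: str = "Cc1cccc(O)c1O"
    chain_length: int = 60
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_complexes < 2:
            raise ValueError("need at least a reference and one target complex")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


# ---------------------------------------------------------------------------
# fixture corpus generation
# ---------------------------------------------------------------------------

def _helix_backbone(n_res: int) -> np.ndarray:
    """Idealized alpha-helix C-alpha trace: 2.3 A radius, 1.5 A rise, 100 deg."""
    i = np.arange(n_res)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _chain_residues(sequence_idx: np.ndarray, ca: np.ndarray) -> list[Residue]:
    residues = []
    serial = 1
    for k in range(len(ca)):
        prev_ = ca[max(k - 1, 0)]
        next_ = ca[min(k + 1, len(ca) - 1)]
        tangent = next_ - prev_
        tangent = tangent / max(np.linalg.norm(tangent), 1e-9)
        name = _AA3[sequence_idx[k]]
        atoms = [
            Atom(serial, "N", "N", ca[k] - 1.46 * tangent),
            Atom(serial + 1, "CA", "C", ca[k]),
            Atom(serial + 2, "C", "C", ca[k] + 1.52 * tangent),
        ]
        serial += 3
        residues.append(Residue(name, k + 1, atoms))
    return residues


def _embed_3d(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse fixture ligand SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed % (2 ** 31 - 1)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"3D embedding failed for {smiles!r}")
    return Chem.RemoveHs(mol)


def _mol_coords(mol: Chem.Mol) -> np.ndarray:
    conf = mol.GetConformer()
    return np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])


def _principal_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed principal-axis frame (columns) of a point cloud."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    frame = vt.T
    if np.linalg.det(frame) < 0:
        frame[:, 2] *= -1
    return frame


def _ligand_from_mol(mol: Chem.Mol, coords: np.ndarray, het_code: str,
                     chain_id: str, resnum: int, serial0: int) -> LigandInstance:
    counts: dict[str, int] = {}
    atoms = []
    for i, at in enumerate(mol.GetAtoms()):
        el = at.GetSymbol()
        counts[el] = counts.get(el, 0) + 1
        atoms.append(Atom(serial0 + i, f"{el.upper()}{counts[el]}", el,
                          coords[i], is_het=True))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), 1.0) for b in mol.GetBonds()]
    return LigandInstance(het_code, chain_id, resnum, atoms, bonds)


def _aromatic_ring_indices(mol: Chem.Mol) -> list[int]:
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            return list(ring)
    return list(range(mol.GetNumAtoms()))


def generate_fixture_corpus(spec: FixtureSpec) -> list[ProteinComplex]:
    """Deterministic toy corpus with planted replacements.

    The reference complex FX00 carries the reference ligand; each target
    FXnn is the same chain under a random rigid motion with Gaussian
    coordinate noise on the protein, carrying one planted fragment whose
    ring is centred and oriented on the reference moiety's ring site.
    """
    rng = np.random.default_rng(spec.seed)
    seq_idx = rng.integers(0, len(_AA3), size=spec.chain_length)
    ca = _helix_backbone(spec.chain_length)

    ref_mol = _embed_3d(spec.reference_ligand_smiles, spec.seed + 1)
    ref_coords = _mol_coords(ref_mol)
    ring = _aromatic_ring_indices(ref_mol)
    site = np.array([10.0, 0.0, 1.5 * spec.chain_length / 2.0])
    ref_coords = ref_coords + (site - ref_coords[ring].mean(axis=0))
    site_frame = _principal_frame(ref_coords[ring])

    complexes = [ProteinComplex(
        "FX00",
        {"A": _chain_residues(seq_idx, ca)},
        [_ligand_from_mol(ref_mol, ref_coords, "CAT", "A", 201,
                          3 * spec.chain_length + 1)],
    )]

    protein_coords = np.vstack([a.coords for r in complexes[0].chains["A"]
                                for a in r.atoms])

    for t in range(1, spec.n_complexes):
        smiles = spec.planted_smiles[(t - 1) % len(spec.planted_smiles)]
        planted = _embed_3d(smiles, spec.seed + 100 + t)
        pl_coords = _mol_coords(planted)
        pl_ring = _aromatic_ring_indices(planted)
        # orient the planted ring onto the reference moiety's ring frame
        rot_align = site_frame @ _principal_frame(pl_coords[pl_ring]).T
        pl_coords = (pl_coords - pl_coords[pl_ring].mean(axis=0)) @ rot_align.T + site

        placed = None
        for _attempt in range(100):
            R = Rotation.random(random_state=np.random.RandomState(
                int(rng.integers(0, 2 ** 31)))).as_matrix()
            tvec = rng.uniform(-15.0, 15.0, size=3)
            noise = rng.normal(0.0, spec.noise_sigma, size=ca.shape)
            moved_protein = (protein_coords @ R.T) + tvec
            moved_ligand = (pl_coords @ R.T) + tvec
            if cdist(moved_ligand, moved_protein).min() >= 1.5:
                placed = (R, tvec, noise)
                break
        if placed is None:
            raise RuntimeError(f"could not place planted fragment {smiles!r} "
                               "without clashing in 100 attempts")
        R, tvec, noise = placed
        residues = _chain_residues(seq_idx, (ca + noise) @ R.T + tvec)
        ligand = _ligand_from_mol(planted, (pl_coords @ R.T) + tvec,
                                  f"P{t:02d}", "A", 201, 3 * spec.chain_length + 1)
        complexes.append(ProteinComplex(f"FX{t:02d}", {"A": residues}, [ligand]))
    return complexes


def write_fixture_corpus(spec: FixtureSpec, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for complex_ in generate_fixture_corpus(spec):
        path = outdir / f"{complex_.entry_id}.pdb"
        path.write_text(write_structure(complex_))
        paths.append(path)
    return paths


def load_corpus(paths: list[str | Path]) -> list[ProteinComplex]:
    corpus = []
    for path in paths:
        path = Path(path)
        corpus.append(parse_structure(path.read_text(), entry_id=path.stem))
    return corpus


# ---------------------------------------------------------------------------
# search orchestration
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    query: str
    fragments: list[ExtractedFragment]
    table: pd.DataFrame
    counts: dict[str, int]
    categories: dict[str, int] = field(default_factory=dict)
    clustering: cc.ClusteringReport | None = None
    curves: dict | None = None
    embedding: np.ndarray | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "results.csv", index=False)
        payload = {
            "query": self.query,
            "counts": self.counts,
            "categories": self.categories,
            "fragments": self.table.to_dict(orient="records"),
        }
        if self.clustering is not None:
            payload["clustering"] = {
                "algorithm": self.clustering.algorithm,
                "hyperparameters": self.clustering.hyperparameters,
                "k": self.clustering.k,
                "silhouette": self.clustering.silhouette,
            }
        (outdir / "results.json").write_text(json.dumps(payload, indent=2))
        if self.fragments:
            (outdir / "fragments.sdf").write_text(fragments_to_sdf(self.fragments))
        if self.categories:
            pd.DataFrame(sorted(self.categories.items(), key=lambda kv: -kv[1]),
                         columns=["category", "count"]).to_csv(
                outdir / "categories.csv", index=False)
        if self.curves is not None:
            cc.plot_tuning_curves(self.curves, str(outdir / "tuning_curves.png"))
        if self.embedding is not None and self.clustering is not None:
            cc.plot_embedding(self.embedding, self.clustering.labels,
                              str(outdir / "embedding.png"))


def _perceive_all(corpus: list[ProteinComplex]) -> None:
    for complex_ in corpus:
        perceived = []
        for ligand in complex_.ligands:
            try:
                perceived.append(perceive_ligand_graph(ligand))
            except ValueError as exc:
                logger.warning("%s %s: ligand perception failed (%s)",
                               complex_.entry_id, ligand.het_code, exc)
                perceived.append(ligand)
        complex_.ligands = perceived


def _reference_moiety(hit: ReferenceHit) -> ExtractedFragment:
    prov = Provenance(hit.complex.entry_id, hit.ligand.het_code,
                      hit.complex.entry_id, hit.ligand.het_code)
    return build_fragment(hit.ligand, sorted(hit.match_atom_indices), prov)


def run_search(query_smiles: str, corpus: list[ProteinComplex],
               config: SearchConfig | None = None) -> SearchResult:
    """Execute the full replacement search over an in-memory corpus."""
    config = config or SearchConfig()
    query = parse_fragment_query(query_smiles)
    _perceive_all(corpus)
    counts = {"complexes": len(corpus)}

    hits = find_reference_hits(corpus, query)
    counts["reference_hits"] = len(hits)
    if not hits:
        logger.warning("no reference ligand contains the query core; nothing to do")
        return SearchResult(query_smiles, [], _table([]), counts)

    candidates: list[ExtractedFragment] = []
    n_homologues = 0
    n_captured_atoms = 0
    for hit in hits:
        reference_moiety = _reference_moiety(hit)
        probes = ProbeSet(
            np.array([hit.ligand.atoms[i].coords for i in hit.match_atom_indices]),
            radius=config.probe_radius)
        pairs = select_homologues(hit, corpus, config.min_identity,
                                  config.min_aligned)
        n_homologues += len(pairs)
        for pair in pairs:
            target = next(c for c in corpus if c.entry_id == pair.target_chain[0])
            try:
                superposed, transform = superpose_by_mapping(
                    target, hit.complex, pair)
            except SuperpositionError as exc:
                logger.warning("skipping %s: %s", target.entry_id, exc)
                continue
            logger.info("superposed %s onto %s: rmsd %.3f A over %d CA",
                        target.entry_id, hit.complex.entry_id,
                        transform.rmsd, transform.n_mapped)
            for ligand in superposed.ligands:
                captured = capture_atoms(probes, ligand)
                n_captured_atoms += len(captured)
                prov = Provenance(hit.complex.entry_id, hit.ligand.het_code,
                                  target.entry_id, ligand.het_code)
                for frag in induce_fragments(ligand, captured, prov,
                                             config.min_atoms):
                    score_fragment(frag, reference_moiety, config.fitness)
                    if frag.smiles == reference_moiety.smiles:
                        frag.self_replacement = True
                    candidates.append(frag)

    counts["homologue_pairs"] = n_homologues
    counts["captured_atoms"] = n_captured_atoms
    counts["captured_fragments"] = len(candidates)

    accepted = filter_rank(candidates, config.fitness)
    counts["post_threshold"] = len(accepted)
    unique = filter_rank(deduplicate(accepted), config.fitness)
    counts["post_dedup"] = len(unique)
    logger.info("stage counts: %s", counts)

    result = SearchResult(query_smiles, unique, _table(unique), counts)
    smiles_list = [f.smiles for f in unique]
    result.categories = cc.category_histogram(smiles_list) if smiles_list else {}

    fps, kept = (cc.fingerprint_set(smiles_list, config.fingerprint)
                 if len(smiles_list) >= 2 else (np.zeros((0, 0)), []))
    if len(kept) >= 4:
        ks = range(2, min(config.max_clusters + 1, len(kept)))
        best_hp, report, curves = cc.tune_clusters(
            fps, config.cluster_algorithm, {"k": ks}, seed=config.seed)
        report.embedding = cc.pca_embed(fps, config.embed_dims)
        result.clustering = report
        result.curves = curves
        result.embedding = report.embedding
        cluster_of = {smi: int(lab) for smi, lab in zip(kept, report.labels)}
        result.table["cluster"] = [cluster_of.get(s, -1) for s in result.table["smiles"]]
    return result


def _table(fragments: list[ExtractedFragment]) -> pd.DataFrame:
    rows = []
    for frag in fragments:
        score = frag.fitness
        rows.append({
            "smiles": frag.smiles,
            "fitness": score.combined if score else np.nan,
            "shape": score.shape if score else np.nan,
            "esp": score.esp if score else np.nan,
            "n_atoms": len(frag.atoms),
            "attachments": frag.attachment_count,
            "category": cc.assign_category(frag.smiles),
            "self_replacement": frag.self_replacement,
            "provenance": ";".join(
                f"{p.reference_entry}:{p.reference_het}->{p.target_entry}:{p.target_het}"
                for p in frag.provenance),
        })
    columns = ["smiles", "fitness", "shape", "esp", "n_atoms", "attachments",
               "category", "self_replacement", "provenance"]
    return pd.DataFrame(rows, columns=columns)
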