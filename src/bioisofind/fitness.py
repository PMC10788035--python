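"""Shape + electrostatic fitness of extracted fragments vs the reference moiety.

Fragments are compared exactly where the superposition left them -- no
re-alignment -- on a [0, 1] scale where 1 is a perfect match:

* shape: Gaussian-volume Tanimoto.  Each heavy atom is an isotropic
  Gaussian whose width scales with its van der Waals radius; pair
  overlap integrals have the closed form
  ``(pi / (a_i + a_j))**1.5 * exp(-a_i a_j d^2 / (a_i + a_j))``.
* electrostatics: Hodgkin similarity of partial-charge-weighted Gaussian
  fields, mapped from [-1, 1] to [0, 1].  Partial charges come from
  Gasteiger iterative electronegativity equalization on the completed
  fragment (attachment wildcards capped with hydrogen).

The combined score is a weighted mean of the two; candidates below the
acceptance threshold (default 0.2) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.distance import cdist

from .extract import ExtractedFragment

#: default combined-score acceptance threshold
DEFAULT_THRESHOLD = 0.2
#: Gaussian width of a carbon atom (A); chosen so the half-density radius
#: sigma * sqrt(2 ln 2) is ~1.7 A, the carbon van der Waals radius
DEFAULT_SHAPE_SIGMA = 1.44
_CARBON_VDW = 1.70


class FitnessError(ValueError):
    pass


@dataclass
class FitnessConfig:
    threshold: float = DEFAULT_THRESHOLD
    shape_sigma: float = DEFAULT_SHAPE_SIGMA
    esp_weight: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if not 0.0 <= self.esp_weight <= 1.0:
            raise ValueError("esp_weight must lie in [0, 1]")
        if self.shape_sigma <= 0:
            raise ValueError("shape_sigma must be positive")


@dataclass
class FitnessScore:
    shape: float
    esp: float
    combined: float


def _alphas(elements: list[str], shape_sigma: float) -> np.ndarray:
    """Gaussian exponents, one per atom, width scaled by vdW radius."""
    sigmas = np.array([
        shape_sigma * gemmi.Element(el).vdw_r / _CARBON_VDW for el in elements
    ])
    return 1.0 / (2.0 * sigmas ** 2)


def _gaussian_overlap_matrix(coords_a, alphas_a, coords_b, alphas_b) -> np.ndarray:
    """S_ij = integral of g_i (set A) times g_j (set B) over all space."""
    d2 = cdist(coords_a, coords_b, "sqeuclidean")
    asum = alphas_a[:, None] + alphas_b[None, :]
    aprod = alphas_a[:, None] * alphas_b[None, :]
    return (np.pi / asum) ** 1.5 * np.exp(-aprod / asum * d2)


def _frag_geometry(frag: ExtractedFragment, shape_sigma: float):
    coords = frag.coords()
    if coords.size == 0:
        raise FitnessError("cannot score an empty fragment")
    elements = [a.element for a in frag.atoms]
    return coords, _alphas(elements, shape_sigma)


def shape_overlap(frag_a: ExtractedFragment, frag_b: ExtractedFragment,
                  shape_sigma: float = DEFAULT_SHAPE_SIGMA) -> float:
    """Gaussian-volume Tanimoto V_AB / (V_AA + V_BB - V_AB) in [0, 1]."""
    ca, aa = _frag_geometry(frag_a, shape_sigma)
    cb, ab = _frag_geometry(frag_b, shape_sigma)
    v_ab = _gaussian_overlap_matrix(ca, aa, cb, ab).sum()
    v_aa = _gaussian_overlap_matrix(ca, aa, ca, aa).sum()
    v_bb = _gaussian_overlap_matrix(cb, ab, cb, ab).sum()
    return float(np.clip(v_ab / (v_aa + v_bb - v_ab), 0.0, 1.0))


def partial_charges(frag: ExtractedFragment) -> np.ndarray:
    """Gasteiger charges per heavy atom, hydrogens condensed onto neighbours.

    Attachment wildcards are capped with hydrogen before the charge
    iteration; atoms Gasteiger cannot parameterize (metal ions) fall back
    to their formal charge.
    """
    if frag.mol is None:
        raise FitnessError("fragment has no completed molecule")
    rw = Chem.RWMol(frag.mol)
    heavy = []
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            rw.ReplaceAtom(atom.GetIdx(), Chem.Atom(1))
        else:
            heavy.append(atom.GetIdx())
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except ValueError as exc:
        raise FitnessError(f"charge assignment failed for {frag.smiles}: {exc}") from exc
    molh = Chem.AddHs(mol)
    AllChem.ComputeGasteigerCharges(molh)
    raw = np.array([float(a.GetProp("_GasteigerCharge")) for a in molh.GetAtoms()])
    formal = np.array([float(a.GetFormalCharge()) for a in molh.GetAtoms()])
    raw = np.where(np.isfinite(raw), raw, formal)
    charges = np.zeros(len(heavy))
    heavy_pos = {idx: k for k, idx in enumerate(heavy)}
    for atom in molh.GetAtoms():
        idx = atom.GetIdx()
        if idx in heavy_pos:
            charges[heavy_pos[idx]] += raw[idx]
        elif atom.GetAtomicNum() == 1:
            for nb in atom.GetNeighbors():
                if nb.GetIdx() in heavy_pos:
                    charges[heavy_pos[nb.GetIdx()]] += raw[idx]
    return charges


def esp_similarity(frag_a: ExtractedFragment, frag_b: ExtractedFragment,
                   shape_sigma: float = DEFAULT_SHAPE_SIGMA,
                   charges_a: np.ndarray | None = None,
                   charges_b: np.ndarray | None = None) -> float:
    """Hodgkin index of the two charge-weighted fields, mapped to [0, 1].

    ``H = 2 <f_a, f_b> / (<f_a, f_a> + <f_b, f_b>)``; two identically
    zero fields count as a perfect match.
    """
    ca, aa = _frag_geometry(frag_a, shape_sigma)
    cb, ab = _frag_geometry(frag_b, shape_sigma)
    qa = partial_charges(frag_a) if charges_a is None else np.asarray(charges_a, float)
    qb = partial_charges(frag_b) if charges_b is None else np.asarray(charges_b, float)
    if qa.shape != (len(ca),) or qb.shape != (len(cb),):
        raise FitnessError("one charge per heavy atom required")
    s_ab = qa @ _gaussian_overlap_matrix(ca, aa, cb, ab) @ qb
    s_aa = qa @ _gaussian_overlap_matrix(ca, aa, ca, aa) @ qa
    s_bb = qb @ _gaussian_overlap_matrix(cb, ab, cb, ab) @ qb
    denom = s_aa + s_bb
    if denom <= 1e-300:
        hodgkin = 1.0
    else:
        hodgkin = float(np.clip(2.0 * s_ab / denom, -1.0, 1.0))
    return (hodgkin + 1.0) / 2.0


def score_fragment(frag: ExtractedFragment, reference: ExtractedFragment,
                   config: FitnessConfig | None = None) -> FitnessScore:
    """Score one candidate against the reference moiety; stores the result."""
    config = config or FitnessConfig()
    shape = shape_overlap(frag, reference, config.shape_sigma)
    esp = esp_similarity(frag, reference, config.shape_sigma)
    combined = (1.0 - config.esp_weight) * shape + config.esp_weight * esp
    score = FitnessScore(shape, esp, float(np.clip(combined, 0.0, 1.0)))
    frag.fitness = score
    return score


def filter_rank(fragments: list[ExtractedFragment],
                config: FitnessConfig | None = None) -> list[ExtractedFragment]:
    """Drop candidates below the threshold; rank survivors.

    Descending combined score; ties broken by fewer heavy atoms, then
    lexicographic SMILES, so equal-scoring outputs are stable.
    """
    config = config or FitnessConfig()
    survivors = [f for f in fragments
                 if f.fitness is not None and f.fitness.combined >= config.threshold]
    return sorted(survivors,
                  key=lambda f: (-f.fitness.combined, len(f.atoms), f.smiles))
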