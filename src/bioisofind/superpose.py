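"""Rigid-body superposition of homologous complexes (Kabsch least squares).

The target complex is brought into the reference frame by fitting the
mapped C-alpha pairs; the resulting proper rotation + translation is then
applied to every atom of the target, ligands included, so that target
ligand fragments can be compared in the reference binding site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .queryhom import HomologuePair
from .structio import ProteinComplex


class SuperpositionError(ValueError):
    pass


@dataclass
class RigidTransform:
    """Maps moving coordinates onto the reference frame: ``x -> R x + t``."""
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_mapped: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_fit(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares proper rotation/translation moving *Q* onto *P*.

    Classic SVD solution with the determinant sign corrected so that no
    reflection is ever returned.  Degenerate (collinear) point sets are
    rejected: the rotation about the common axis would be arbitrary.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError("point sets must be matching (n, 3) arrays")
    n = len(P)
    if n < 3:
        raise SuperpositionError(f"need at least 3 point pairs, got {n}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    sv_p = np.linalg.svd(Pc, compute_uv=False)
    sv_q = np.linalg.svd(Qc, compute_uv=False)
    if sv_p[1] < 1e-8 * max(sv_p[0], 1.0) or sv_q[1] < 1e-8 * max(sv_q[0], 1.0):
        raise SuperpositionError("degenerate (collinear) point set")
    H = Qc.T @ Pc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - R @ Q.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((Q @ R.T + t - P) ** 2, axis=1))))
    return RigidTransform(R, t, rmsd, n)


def superpose_by_mapping(target: ProteinComplex, reference: ProteinComplex,
                         pair: HomologuePair) -> tuple[ProteinComplex, RigidTransform]:
    """Superpose *target* onto *reference* using the mapped residues.

    Fits C-alpha atoms of the residue pairs in ``pair.residue_map`` and
    applies the transform to a deep copy of the whole target complex.
    """
    ref_cid = pair.reference_chain[1]
    tgt_cid = pair.target_chain[1]
    ref_by_num = {r.number: r for r in reference.chains[ref_cid]}
    tgt_by_num = {r.number: r for r in target.chains[tgt_cid]}
    P, Q = [], []
    for ref_num, tgt_num in pair.residue_map:
        ra = ref_by_num.get(ref_num)
        ta = tgt_by_num.get(tgt_num)
        if ra is None or ta is None:
            continue
        ca_r, ca_t = ra.atom("CA"), ta.atom("CA")
        if ca_r is None or ca_t is None:
            continue
        P.append(ca_r.coords)
        Q.append(ca_t.coords)
    if len(P) < 3:
        raise SuperpositionError(
            f"{target.entry_id}->{reference.entry_id}: fewer than 3 usable CA pairs")
    transform = kabsch_fit(np.array(P), np.array(Q))
    return target.transformed(transform.rotation, transform.translation), transform
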