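"""Categorize, fingerprint, cluster and embed accepted replacement fragments.

Fragments are first binned into human-readable composition categories
derived from their SMILES ("cycle C+O+N", "acyclic C+O", single-element
bins like "F").  For chemical-space analysis they become 2048-bit Morgan
(circular, radius 2) fingerprints; pairwise Tanimoto distances feed the
unsupervised algorithms, cluster-number tuning (elbow SSE + silhouette)
and a PCA projection to 2-3 dimensions for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.cluster import (DBSCAN, OPTICS, AffinityPropagation,
                             AgglomerativeClustering, Birch, KMeans, MeanShift)
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

logger = logging.getLogger(__name__)

#: elements joined in this order when naming composition categories
_ELEMENT_PRIORITY = ["C", "O", "N", "S", "P", "B", "F", "Cl", "Br", "I"]

#: predefined composition vocabularies; anything else maps to the
#: corresponding "other" bin.  Exposed as configuration because the
#: printed category list is a reporting choice, not chemistry.
DEFAULT_CYCLIC_SETS = [
    {"C"}, {"C", "N"}, {"C", "O"}, {"C", "S"},
    {"C", "O", "N"}, {"C", "N", "S"}, {"C", "O", "S"},
]
DEFAULT_ACYCLIC_SETS = [
    {"C"}, {"C", "O"}, {"C", "N"}, {"C", "O", "N"},
    {"C", "S"}, {"C", "O", "P"}, {"C", "F"}, {"C", "Cl"},
]

_CLUSTER_COUNT_ALGORITHMS = {"kmeans", "agglomerative", "spectral"}
_DENSITY_ALGORITHMS = {"meanshift", "birch", "optics", "dbscan", "affinity_propagation"}
#: algorithms whose model is a set of centroids, for which SSE is meaningful
_CENTROID_ALGORITHMS = {"kmeans", "meanshift", "birch"}


@dataclass
class FingerprintConfig:
    n_bits: int = 2048
    radius: int = 2

    def __post_init__(self):
        if self.n_bits & (self.n_bits - 1):
            raise ValueError("n_bits must be a power of two")


@dataclass
class ClusteringReport:
    algorithm: str
    hyperparameters: dict
    labels: np.ndarray
    k: int
    sse: float | None = None
    silhouette: float | None = None
    embedding: np.ndarray | None = None


# ---------------------------------------------------------------------------
# SMILES composition categories
# ---------------------------------------------------------------------------

def _element_set_name(elements: set[str]) -> str:
    rank = {el: i for i, el in enumerate(_ELEMENT_PRIORITY)}
    ordered = sorted(elements, key=lambda el: (rank.get(el, len(rank)), el))
    return "+".join(ordered)


def assign_category(smiles: str,
                    cyclic_sets: list[set[str]] | None = None,
                    acyclic_sets: list[set[str]] | None = None) -> str:
    """Composition category of one fragment SMILES.

    Single heavy atoms are labelled by element ("F"); ring-bearing
    fragments get "cycle <elements>" if their heavy-element set is in the
    predefined vocabulary, else "cycle other"; acyclic fragments behave
    analogously.  Attachment wildcards are ignored.
    """
    cyclic_sets = DEFAULT_CYCLIC_SETS if cyclic_sets is None else cyclic_sets
    acyclic_sets = DEFAULT_ACYCLIC_SETS if acyclic_sets is None else acyclic_sets
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() not in (0, 1)]
    if not heavy:
        raise ValueError(f"{smiles!r} has no heavy atoms")
    if len(heavy) == 1:
        return heavy[0].GetSymbol()
    elements = {a.GetSymbol() for a in heavy}
    if mol.GetRingInfo().NumRings() > 0:
        if elements in cyclic_sets:
            return f"cycle {_element_set_name(elements)}"
        return "cycle other"
    if elements in acyclic_sets:
        return f"acyclic {_element_set_name(elements)}"
    return "acyclic other"


def category_histogram(smiles_list: list[str], **kwargs) -> dict[str, int]:
    counts: dict[str, int] = {}
    for smi in smiles_list:
        label = assign_category(smi, **kwargs)
        counts[label] = counts.get(label, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


# ---------------------------------------------------------------------------
# fingerprints and distances
# ---------------------------------------------------------------------------

def clean_smiles(smiles_list: list[str]) -> list[str]:
    """Drop empty entries and duplicates, preserving first-seen order."""
    seen: set[str] = set()
    out = []
    for smi in smiles_list:
        if not smi or smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
    return out


def fingerprint_set(smiles_list: list[str],
                    config: FingerprintConfig | None = None
                    ) -> tuple[np.ndarray, list[str]]:
    """Morgan fingerprints for a cleaned SMILES list.

    Returns the (n, n_bits) uint8 bit matrix and the SMILES actually
    fingerprinted; unparseable rows are dropped with a warning.
    """
    config = config or FingerprintConfig()
    generator = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits)
    rows, kept = [], []
    for smi in clean_smiles(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("dropping unparseable SMILES %r", smi)
            continue
        rows.append(generator.GetFingerprintAsNumPy(mol))
        kept.append(smi)
    if not rows:
        return np.zeros((0, config.n_bits), dtype=np.uint8), []
    return np.vstack(rows).astype(np.uint8), kept


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Tanimoto on binary fingerprints; all-zero pairs -> 0."""
    fps = np.asarray(fps, dtype=np.float64)
    if fps.ndim != 2 or len(fps) < 2:
        raise ValueError("need a matrix of at least two fingerprints")
    inter = fps @ fps.T
    pop = fps.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _sse(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean errors around centroids."""
    total = 0.0
    for lab in np.unique(labels):
        if lab < 0:
            continue
        members = X[labels == lab]
        total += float(((members - members.mean(axis=0)) ** 2).sum())
    return total


def _make_estimator(algorithm: str, hp: dict, seed: int):
    if algorithm == "kmeans":
        return KMeans(n_clusters=hp.get("k", 8), n_init=20, random_state=seed)
    if algorithm == "agglomerative":
        return AgglomerativeClustering(n_clusters=hp.get("k", 2))
    if algorithm == "spectral":
        return SpectralClustering(n_clusters=hp.get("k", 8), random_state=seed,
                                  assign_labels="discretize")
    if algorithm == "meanshift":
        return MeanShift(bandwidth=hp.get("bandwidth"))
    if algorithm == "birch":
        return Birch(threshold=hp.get("threshold", 0.5), n_clusters=None)
    if algorithm == "optics":
        return OPTICS(min_samples=hp.get("min_samples", 5))
    if algorithm == "dbscan":
        return DBSCAN(eps=hp.get("eps", 0.5), min_samples=hp.get("min_samples", 5))
    if algorithm == "affinity_propagation":
        return AffinityPropagation(random_state=seed,
                                   damping=hp.get("damping", 0.5))
    raise ValueError(f"unknown clustering algorithm {algorithm!r}")


def run_clustering(fps: np.ndarray, algorithm: str,
                   hyperparameters: dict | None = None, seed: int = 0,
                   distance: np.ndarray | None = None) -> ClusteringReport:
    """Fit one unsupervised algorithm on raw fingerprint vectors.

    The silhouette is always evaluated on the Tanimoto distance matrix
    (passed in or computed here) so scores are comparable across
    algorithms; SSE is reported for the centroid-model algorithms.
    """
    hp = dict(hyperparameters or {})
    fps = np.asarray(fps, dtype=float)
    n = len(fps)
    if "k" in hp and hp["k"] > n:
        raise ValueError(f"k={hp['k']} exceeds the {n} available points")
    est = _make_estimator(algorithm, hp, seed)
    labels = np.asarray(est.fit_predict(fps))
    k = len({lab for lab in labels.tolist() if lab >= 0})
    report = ClusteringReport(algorithm, hp, labels, k)
    if algorithm in _CENTROID_ALGORITHMS:
        report.sse = _sse(fps, labels)
    if distance is None:
        distance = tanimoto_distance_matrix(fps)
    mask = labels >= 0
    n_labels = len({lab for lab in labels[mask].tolist()})
    if 2 <= n_labels < int(mask.sum()):
        report.silhouette = silhouette_mean(distance[np.ix_(mask, mask)], labels[mask])
    return report


def silhouette_mean(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b) on a distance matrix.

    Singleton clusters contribute 0 by convention; a single cluster
    overall is an error because b(i) is undefined.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("silhouette needs at least two clusters")
    samples = silhouette_samples(np.asarray(D, dtype=float), labels,
                                 metric="precomputed")
    return float(samples.mean())


def tune_clusters(fps: np.ndarray, algorithm: str,
                  search: dict | None = None, seed: int = 0,
                  sse_ratio_limit: float = 0.5):
    """Hyperparameter tuning with elbow + silhouette curves.

    For cluster-count algorithms the candidate with the best silhouette
    (on Tanimoto distances) wins, unless the winner is k=2 while its SSE
    is still more than *sse_ratio_limit* of the single-cluster SSE -- a
    sign the silhouette rewarded separation only -- in which case the
    next-best silhouette is taken.  For density/bandwidth algorithms the
    silhouette argmax over the searched hyperparameter values wins.

    Returns ``(best_hyperparameters, best_report, curves)``.
    """
    fps = np.asarray(fps, dtype=float)
    n = len(fps)
    D = tanimoto_distance_matrix(fps)
    search = dict(search or {})

    if algorithm in _CLUSTER_COUNT_ALGORITHMS:
        ks = list(search.get("k", range(2, min(11, n))))
        if not ks:
            raise ValueError("empty search space")
        sse_total = _sse(fps, np.zeros(n, dtype=int))
        reports, sses, silhouettes = [], [], []
        for k in ks:
            rep = run_clustering(fps, algorithm, {"k": k}, seed=seed, distance=D)
            if rep.sse is None:
                rep.sse = _sse(fps, rep.labels)
            reports.append(rep)
            sses.append(rep.sse)
            silhouettes.append(rep.silhouette if rep.silhouette is not None else -np.inf)
        curves = {"k": ks, "sse": sses, "silhouette": silhouettes,
                  "sse_total": sse_total}
        order = np.argsort(silhouettes)[::-1]
        best = int(order[0])
        if (ks[best] == 2 and len(order) > 1
                and sses[best] > sse_ratio_limit * sse_total):
            best = int(order[1])
        if not np.isfinite(silhouettes[best]):
            raise ValueError("no candidate produced a valid clustering")
        return {"k": ks[best]}, reports[best], curves

    if algorithm in _DENSITY_ALGORITHMS:
        param = search.get("param", {"meanshift": "bandwidth", "birch": "threshold",
                                     "optics": "min_samples", "dbscan": "eps",
                                     "affinity_propagation": "damping"}[algorithm])
        values = list(search.get("values", []))
        if not values:
            raise ValueError(f"provide search values for {algorithm}.{param}")
        reports, silhouettes = [], []
        for v in values:
            try:
                rep = run_clustering(fps, algorithm, {param: v}, seed=seed, distance=D)
            except ValueError:
                rep = None
            reports.append(rep)
            silhouettes.append(rep.silhouette
                               if rep is not None and rep.silhouette is not None
                               else -np.inf)
        curves = {param: values, "silhouette": silhouettes,
                  "k": [r.k if r is not None else 0 for r in reports]}
        best = int(np.argmax(silhouettes))
        if not np.isfinite(silhouettes[best]):
            raise ValueError(
                f"all {algorithm} candidates degenerate: ks="
                f"{[r.k if r is not None else None for r in reports]}")
        return {param: values[best]}, reports[best], curves

    raise ValueError(f"unknown clustering algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def pca_embed(fps: np.ndarray, dims: int = 2) -> np.ndarray:
    """Principal-component projection of centered fingerprint vectors.

    Component signs are fixed (largest-magnitude loading positive) so the
    embedding is fully deterministic.
    """
    fps = np.asarray(fps, dtype=float)
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if len(fps) < dims + 1:
        raise ValueError(f"need at least {dims + 1} points for a {dims}-D embedding")
    pca = PCA(n_components=dims, svd_solver="full")
    scores = pca.fit_transform(fps)
    for c in range(dims):
        loadings = pca.components_[c]
        if loadings[np.argmax(np.abs(loadings))] < 0:
            scores[:, c] *= -1.0
    return scores


# ---------------------------------------------------------------------------
# synthetic fingerprint data for calibration and testing
# ---------------------------------------------------------------------------

def synthetic_fingerprint_blobs(n_groups: int, n_points: int = 200,
                                n_bits: int = 2048, bits_on: int = 60,
                                n_flips: int = 3, seed: int = 0
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Planted fingerprint clusters: group prototypes with per-point bit flips.

    Each group gets a random prototype with *bits_on* set bits; members
    flip *n_flips* random bits.  Prototypes of different groups share
    almost no bits at these densities, so the planted partition is far
    better separated than the within-group spread.
    """
    rng = np.random.default_rng(seed)
    prototypes = np.zeros((n_groups, n_bits), dtype=np.uint8)
    for g in range(n_groups):
        prototypes[g, rng.choice(n_bits, size=bits_on, replace=False)] = 1
    labels = np.repeat(np.arange(n_groups), -(-n_points // n_groups))[:n_points]
    fps = prototypes[labels].copy()
    for i in range(n_points):
        flips = rng.choice(n_bits, size=n_flips, replace=False)
        fps[i, flips] ^= 1
    return fps, labels


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_tuning_curves(curves: dict, path: str) -> None:
    """SSE-elbow and silhouette curves side by side."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x_key = "k" if "k" in curves and "sse" in curves else next(iter(curves))
    has_sse = "sse" in curves
    fig, axes = plt.subplots(1, 2 if has_sse else 1, figsize=(9, 3.5), squeeze=False)
    if has_sse:
        axes[0][0].plot(curves["k"], curves["sse"], "o-")
        axes[0][0].set_xlabel("number of clusters k")
        axes[0][0].set_ylabel("SSE")
        axes[0][1].plot(curves["k"], curves["silhouette"], "o-")
        axes[0][1].set_xlabel("number of clusters k")
        axes[0][1].set_ylabel("mean silhouette")
    else:
        axes[0][0].plot(curves[x_key], curves["silhouette"], "o-")
        axes[0][0].set_xlabel(x_key)
        axes[0][0].set_ylabel("mean silhouette")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_embedding(embedding: np.ndarray, labels: np.ndarray, path: str) -> None:
    """2-D or 3-D scatter of the PCA chemical-space embedding."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    embedding = np.asarray(embedding)
    fig = plt.figure(figsize=(5, 4.5))
    if embedding.shape[1] == 3:
        ax = fig.add_subplot(projection="3d")
        ax.scatter(embedding[:, 0], embedding[:, 1], embedding[:, 2],
                   c=labels, cmap="tab10", s=18)
        ax.set_zlabel("PC3")
    else:
        ax = fig.add_subplot()
        ax.scatter(embedding[:, 0], embedding[:, 1], c=labels, cmap="tab10", s=18)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
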