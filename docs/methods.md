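# Methods

## The search model

`bioisofind` operationalizes a simple structural argument: after two
homologous binding sites are superposed, any ligand fragment of the
second complex that occupies the region of a chosen moiety in the first
is an experimentally observed local structural replacement for that
moiety. The pipeline therefore has two geometric primitives — rigid
superposition and sphere capture — wrapped in chemistry bookkeeping
(graph perception, valence completion, canonicalization) and followed by
statistical post-processing (fitness scoring, categorization,
clustering).

### Structure model

PDB input is reduced to heavy atoms of the first model. One altloc is
kept per atom (highest occupancy; ties resolved toward conformer "A").
Waters are discarded; every other HETATM residue becomes a ligand
instance, including single metal ions — metals can participate directly
in a replacement (a cation plus a small group can stand in for a charged
moiety), so they are kept and exempted from the minimum-size filter.
Polymer membership is decided by backbone atoms (N/CA/C), so
nonstandard residues such as MSE stay in the chain and map to `X` in
sequences.

### Ligand graph perception

Bonds are the union of file CONECT records and a covalent-radius rule:
two heavy atoms bond iff their distance is at most the sum of covalent
radii + 0.4 Å (a clash error is raised below 0.5 Å). Bond orders are
then assigned geometrically: planar 5–7 membered rings of C/N/O/S
(out-of-plane RMS ≤ 0.1 Å, ring-atom degree ≤ 3) are flagged aromatic
and validated by RDKit sanitization, with a pyrrole-type NH retry when
kekulization needs it; remaining short bonds are promoted to double or
triple using per-element-pair length cutoffs subject to free valence;
if sanitization still fails the ligand falls back to a single-bonded
graph. This in-repo perception exists because hydrogen-free crystal
ligands defeat hydrogen-assuming order assignment; it is deliberately
conservative and is cross-checked in the tests against RDKit-embedded
geometries and an independent toolkit.

### Homology and superposition

Blast-style database search is replaced by exact global pairwise
alignment (BLOSUM62, affine gaps open 11 / extend 1) because the corpus
here is a directory, not the PDB. Identity is counted over aligned
(non-gap) columns. Defaults — ≥ 90 % identity over ≥ 50 aligned
residues, best chain pair per target — encode "very close or identical
structure"; both are flags. Superposition is plain Kabsch least squares
on mapped Cα atoms with the reflection excluded; the transform moves
every target atom. TM-score-weighted alignment is intentionally not
implemented: superposition here only needs to bring binding sites into
one frame, and least squares is exactly testable against independent
numerical minimization.

### Capture and completion

Each matched reference-moiety atom centres a probe sphere of radius
2.5 Å; membership is a closed ball (an atom exactly at the radius is
captured). Captured target-ligand atoms are split into connected
components; each bond to an uncaptured neighbour is cut and becomes a
wildcard attachment; components under 3 heavy atoms (configurable) are
discarded as noise, metals excepted. Valence left open by the cuts is
filled with implicit hydrogens and the fragment canonicalized, so
isomorphic captures from different entries collapse to one SMILES at
deduplication (best fitness kept, provenances merged).

### Fitness

The published workflow treats its overlap scorer as a black box with a
fixed contract: range [0, 1], 1 = perfect match, acceptance threshold
0.2. This package keeps the contract with an explicit, closed-form
scorer:

* **Shape** — Gaussian-volume Tanimoto. Atom *i* contributes
  `exp(−α_i‖r−c_i‖²)` with `α_i = 1/(2σ_i²)` and `σ_i` scaled by the
  atom's van der Waals radius; the default carbon width 1.44 Å puts the
  half-density radius at ≈ 1.7 Å (the carbon vdW radius). Pair overlap
  integrals are analytic, so self-similarity is exactly 1.
* **Electrostatics** — Hodgkin index `2⟨f_a,f_b⟩/(⟨f_a,f_a⟩+⟨f_b,f_b⟩)`
  of partial-charge-weighted Gaussian fields, mapped from [−1, 1] to
  [0, 1]. Charges are Gasteiger (iterative electronegativity
  equalization) on the completed fragment with attachments capped by
  hydrogen, hydrogen charges condensed onto their heavy atom; atoms
  outside the Gasteiger parameterization (metal ions) fall back to
  formal charge. Two identically zero fields score 1.
* **Combined** — arithmetic mean by default (`esp_weight` 0.5), filtered
  at `combined ≥ 0.2`; the threshold is applied to the combined score.
  Ties in ranking break toward fewer heavy atoms, then lexicographic
  SMILES, so output order is fully deterministic.

Fragments are scored exactly where superposition put them; no
re-alignment is performed, because spatial coincidence in the protein
frame is the evidence being scored. Donor/acceptor directionality is
deliberately not modelled — the score tracks conservation of the
interaction region, not its polarity sign conventions.

### Categories, clustering, embedding

Composition categories are named from the heavy-element set, joined in
the fixed order C, O, N, S, P, B, halogens (hence "cycle C+O+N"), with
"cycle"/"acyclic" prefixes and single-atom bins named by element. The
predefined element-set vocabularies are configuration, not constants,
because the canonical published category count is ambiguous (24 vs 32
groups in different places); anything unlisted maps to "cycle other" /
"acyclic other", and the labels partition any input set.

Fingerprints are 2048-bit Morgan, radius 2 (the radius is our choice;
the bit width is the published one). Cluster algorithms (k-means,
agglomerative, spectral, mean-shift, Birch, OPTICS, DBSCAN, affinity
propagation) run on the raw binary vectors in Euclidean space, while
silhouettes are always evaluated on the Tanimoto distance matrix so
algorithms are comparable; both choices are flags. k-means uses
k-means++ with 20 restarts and a fixed seed. Cluster-number selection
takes the silhouette argmax over k, with one guard: if k = 2 wins while
its SSE still exceeds half the single-cluster SSE, the silhouette has
rewarded separation alone and the next-best k is taken (the published
"retreat from k = 2" heuristic, given an explicit ratio of 0.5 here
because no number was published). Mean-shift-style algorithms are tuned
by silhouette over an explicit hyperparameter list. PCA embeddings fix
each component's sign (largest-magnitude loading positive) so plots are
reproducible bit-for-bit.

Reported silhouette optima from the original corpus (e.g. 0.561 for
mean-shift at bandwidth 446) are not reproduction targets: that feature
space/metric combination is under-specified, and a bandwidth of 446 is
not interpretable on 2048-bit binary vectors whose maximal Euclidean
distance is ≈ 45.

## Synthetic fixtures: what they emulate and what they do not

`FixtureSpec` generates one reference complex and n−1 homologues. The
protein is an idealized α-helix Cα trace (2.3 Å radius, 1.5 Å rise,
100°/residue) with schematic N and C backbone atoms, 60 residues by
default — comfortably above the 50-aligned-residue homology floor — and
a random but seed-fixed sequence shared by all members. The reference
ligand (3-methylcatechol by default) is ETKDG-embedded and parked 10 Å
off the helix axis; each homologue carries a planted fragment
(pyridine by default) whose ring is centred and principal-axis-aligned
on the reference moiety's ring site, then the whole complex is moved by
a random rigid motion with Gaussian noise (σ = 0.1 Å by default, the
coordinate scale of close crystallographic homologues) on the protein
atoms. Placement retries up to 100 times if the ligand comes within
1.5 Å of the protein.

Fixtures therefore exercise every pipeline stage — parsing, perception,
matching, alignment, superposition, capture, scoring, clustering — with
a known ground truth. They do **not** emulate real binding sites:
there are no side chains, no pocket enclosure, no induced fit, no
crystallographic disorder, and planted fragments are placed to overlap
the moiety rather than bound by physics. Passing the planted-recovery
tests demonstrates the machinery is correct and calibrated end-to-end,
not that real-PDB scans will reach any particular yield; yields on real
corpora depend on the deposited snapshot and are out of scope.

## Numerical choices and degenerate inputs

* Kabsch rejects < 3 point pairs and collinear sets (second singular
  value < 1e−8 of the first): the in-plane rotation would be arbitrary.
* Capture is a closed ball; enlarging the radius can only grow the set.
* Tanimoto distance between two all-zero fingerprints is 0 by
  convention (identical objects), and the matrix is symmetrized and
  clipped to [0, 1] against floating-point drift.
* Silhouette requires ≥ 2 clusters and ≥ 1 non-singleton; singleton
  clusters score 0; the all-singletons case (k = n) is reported with
  SSE = 0 and no silhouette.
* Fragments that cannot keep partial aromatic flags after capture are
  rebuilt kekulized-out (single bonds); an impossible-valence fragment
  raises an error carrying its provenance rather than silently
  vanishing.
* Problem sizes in the test and acceptance runs (corpora of 4–6
  complexes, 60-residue chains, 200-point fingerprint sets, 10 recovery
  seeds) were chosen as the smallest sizes at which every stage is
  exercised with non-trivial geometry and statistics.

## Known limitations

* Bond-order perception is geometric and heavy-atom-only; exotic
  ligands (extended conjugation, unusual oxidation states) may fall
  back to single-bonded graphs, which weakens ESP scoring for them.
* Sequence-only homologue selection misses structure-conserving remote
  homologues a structure-based aligner would find.
* One chain pair per target is superposed; multimeric pockets formed
  across chain interfaces are only partially handled.
* Attachment compatibility of a suggested replacement with the parent
  scaffold is reported (attachment count) but not enforced; re-merging
  fragments into full ligands is out of scope.
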