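# Methods

This note documents the models and procedures the toolkit implements, the
conventions it pins where several are defensible, and what its synthetic
test data does and does not establish about real challenge data.

## Data model

The canonical molecular representation is the **heavy-atom graph**: element
labels, formal charges, bonds, and optional Å coordinates. Hydrogens are
dropped on ingestion (their per-atom count is retained so molecules
round-trip through SMILES and aromatic perception such as pyrrole N–H
survives), because pose accuracy is defined against heavy-atom crystal
positions. Coordinates are stored exactly as read from PDB/SDF — no
recentering — so the superposition module owns every transform.
Stereochemistry is parsed but never used in graph matching: screening
compounds are typically supplied as racemic mixtures, and either enantiomer
may be the crystallographically resolved one.

Boolean screening submissions use a strict dialect
(`True/False/true/false/1/0`); anything else is an error with a row number.
Blind-challenge submissions must be unambiguous, and silent coercion of
`yes`/`y`/`T` is a classic source of mis-scored entries.

## Superposition

`kabsch_fit` minimizes Σ‖Rx+t−y‖² over proper rotations by SVD of the
centered covariance, with the standard determinant correction (flip the
smallest singular direction when the unconstrained optimum is a
reflection). This guarantees det R = +1 even for near-planar point sets, so
a ligand can never be silently mirrored. All points are weighted equally —
the evaluation calls for a plain Cα alignment, not a B-factor-weighted one.

Cα pairing between predicted and reference receptors is by
(chain id, residue number) intersection, **not** sequence alignment: the
challenge receptors are the same construct, so a numbering mismatch is a
file problem worth surfacing (`PairingError` lists the unmatched residues).
Alignment uses all common Cα by default; a residue-range filter supports
binding-site-only alignment. Fewer than 3 common pairs is an error;
collinear sets produce a warning (rotation about the axis is unconstrained)
but still return the fit.

## Symmetry-corrected RMSD

The pose deviation is min over σ of √(mean_k ‖x_pred,σ(k) − x_ref,k‖²),
where σ ranges over all isomorphisms of the element-labeled heavy-atom
graphs. The implementation enumerates the complete mapping set by
backtracking with element/degree/adjacency pruning — full enumeration, not
a single mapping, because the minimum is over all of them. Fragments are
small (≲ 30 heavy atoms), so correctness is cheap; a configurable 64-node
cap guards against accidental use on polymers.

Conventions:

* **Bond orders are ignored by default** (configurable). Docking outputs
  and crystallographic models frequently disagree on bond-order perception;
  element + topology is the robust common denominator.
* **No re-superposition per mapping.** RMSD is computed in the frame fixed
  by the Cα alignment, matching the evaluation's order of operations
  (align receptors once, then measure ligand deviation).
* Ties between mappings break toward the lexicographically smallest
  permutation, making the reported mapping deterministic.
* A predicted molecule whose heavy-atom graph differs from the reference
  (wrong tautomer, wrong compound) is an error, never a guessed partial
  mapping; in pose evaluation such poses are recorded and excluded while
  the fragment stays in the denominator.

Tests verify the search against an exhaustive permutation oracle
(permutations within element classes, edge-preservation checked directly)
on a 20-molecule panel, and the automorphism group against networkx's VF2
matcher.

## Screening metrics and the bootstrap

Excluded fragments (no usable diffraction data) are removed before any
metric. Sensitivity, specificity and balanced accuracy come from the 2×2
confusion table; if a ground truth has no positives (or negatives) the
undefined rate is reported as missing rather than imputed, and balanced
accuracy is not computed.

Confidence intervals use the **percentile bootstrap** (2.5th/97.5th
percentiles at the 0.95 level, 10,000 resamples by default), resampling the
(prediction, label) pairs jointly — not stratified by class, which is the
plain reading of resampling a submission array. Because a with-replacement
resample of paired binary arrays is fully characterized by its four
confusion-cell counts, the implementation draws the resamples directly as a
multinomial over (TP, FN, TN, FP); this is distributionally identical to
index resampling and makes the 10,000-resample computation vectorizable.
Resamples that draw no positives (or no negatives) leave a rate undefined;
they are discarded and their count is reported in the CI object, avoiding a
silent bias. A single seeded generator makes every CI bit-reproducible.

Cross-submission summaries report mean, SD and SEM explicitly labeled,
because "mean ± x" summaries are ambiguous about which spread x denotes.

## Pose bookkeeping

Success is RMSD ≤ cutoff with an **inclusive** comparison at 2.0 Å by
default. Where sources state the rule both as "≤ 2 Å" and "less than 2 Å",
the methods-level statement (inclusive) wins; the comparison is a flag for
users who disagree. The success denominator defaults to the evaluated rows
but can be pinned to the full stage size, so a submission that skipped
fragments is scored against the whole task. Curves are evaluated on a
strictly increasing grid (default 0–6 Å, 0.1 Å steps) and are monotone by
construction.

## Descriptors

Definitions are pinned to one published convention so results are
reproducible: Wildman–Crippen logP, Ertl TPSA, HBD = N/O bearing ≥ 1 H,
HBA = N/O excluding pyrrole-type and amide nitrogens, rotatable bond =
acyclic single bond between non-terminal heavy atoms excluding amide C–N,
ring count = SSSR size (all as implemented by RDKit's curated descriptor
set). Fingerprints are radius-2 circular environments kept as a *set* of
hashed identifiers; Tanimoto is set Jaccard, defined as 1 when both sets
are empty. Count-insensitive fingerprints slightly compress similarity for
molecules with repeated motifs; since similarity summaries here are
cohort-level diagnostics, the simpler convention is preferred. Fingerprint
hashing parameters are not standardized across toolkits, so absolute
Tanimoto averages (e.g. a library-wide ~0.23) are not exact targets.

Rule-of-5 compliance follows the classic allowance (≤ 1 violation of
MW > 500, logP > 5, HBD > 5, HBA > 10); a strict zero-violation mode is a
flag.

## Fragment network

Fragmentation dialect (the operative rules, since "removal of substituents,
rings and linkers" admits several): every **acyclic single bond** (never an
aromatic or ring bond) is splittable; both sides of a cut, hydrogen-capped
and canonicalized, become children if they retain ≥ 1 heavy atom. Nodes are
plain canonical structures; the attachment-annotated fragment (cut position
marked with `*`) is kept as the **edge label**. Putting attachment marks on
the edge rather than in the node form keeps a library molecule and the
identical core reached by fragmenting a larger molecule as *one* node —
necessary for queries anchored at such cores to reach their elaborations —
and preserves the invariant that heavy-atom count strictly decreases along
every edge (hence the graph is acyclic).

Query semantics: undirected breadth-first traversal to ≤ `hops` edges;
results are library molecules whose |Δ heavy atoms| ≤ `hac` and
|Δ ring atoms| ≤ `rac` **versus the query molecule** (not per hop), sorted
by (distance, canonical form). Results are monotone in each parameter. A
query not present in the network is anchored on its direct fragmentation
children that the network contains (at distance 1); a query sharing no
fragments returns empty with a warning. Aggregated multi-query results are
deduplicated by canonical form, keeping the smallest distance.

Storage is an in-process networkx graph serialized to line-oriented JSON.
Desk-scale libraries (10²–10⁴ molecules) need no graph database; the
40-million-molecule commercial networks this emulates are out of scope.

## Synthetic data and what passing tests show

The fixtures module generates the study conditions used throughout the
tests and the acceptance script:

* **Ground truth** at the published bookkeeping: a 799-fragment library
  with 52 hits across all sites / 47 at the acetyl-lysine site and 40
  exclusions — giving 707 / 712 negatives and hit rates 6.51% / 5.88%.
* **Toy libraries** from a template grammar (ring cores × substituent
  menu), 3–25 heavy atoms, deterministic per seed. These emulate
  fragment-sized chemotypes, not any real vendor library.
* **Perturbed poses** built from tabulated idealized geometries (hexagonal
  benzene, para-disubstituted ring, ethanol) under seeded rigid motions and
  Gaussian noise, with the exact naive RMSD computed directly from the
  perturbation — a ground truth independent of the RMSD code under test.
  Oracle-equivalence panels attach seeded random coordinates to parsed
  graphs; RMSD minimization only sees a labeled graph plus points, so
  chemical realism of the geometry is irrelevant there.
* **Simulated submissions** correct on each positive with probability equal
  to the target sensitivity and on each negative with the target
  specificity. Coverage studies use sensitivity 0.6 / specificity 0.9 at
  n = 759 (47 positives, 712 negatives), the realistic regime where the
  sensitivity term dominates the CI width.
* **Synthetic receptor**: an ideal α-helix of Cα pseudo-atoms (1.5 Å rise,
  100°/residue, 2.3 Å radius) — sufficient for superposition tests, not a
  protein model.

Passing these suites establishes that the machinery is correct: metrics
match independent implementations, the symmetry search equals exhaustive
enumeration, alignment recovers exact rigid motions, bootstrap intervals
achieve nominal coverage under the simulated data-generating process, and
the network obeys its structural invariants. It does **not** establish
per-method results on the real challenge (per-submission balanced
accuracies, per-submission pose success rates, the real library's
similarity profile): those require the externally archived submission files,
deposited crystal structures and vendor library, which the toolkit can
consume through the same interfaces when available.

## Problem sizes and numerical choices

Default study sizes — 20-molecule oracle panels (≤ 10 heavy atoms), 100
random rigid motions, 1000 random-predictor seeds, 500 × 10,000-resample
coverage replicates, 50-molecule network libraries — are chosen so the
whole suite completes in seconds while Monte-Carlo error stays well inside
the asserted tolerances (e.g. the random-baseline mean is tested at ±0.02
where its standard error is ≈ 0.001). Exact-arithmetic checks use 1e-9–1e-12
absolute tolerances; geometry recovery uses 1e-6 Å; file round-trips use the
format's printed precision (1e-3 Å for SDF). Degenerate inputs are handled
explicitly: collinear Cα sets warn, empty cohorts and empty resample sets
raise, and per-pose failures never abort a stage.

## Known limitations

* PDB support is the ATOM/HETATM subset (first model, first altloc after
  gemmi's alternative-conformation pruning); no mmCIF, no anisotropic data.
* RMSD requires graph-isomorphic molecules; there is no maximum-common-
  substructure partial scoring and no per-mapping re-superposition
  (Hungarian-style variants are deliberately out of scope).
* The fragmentation dialect is one operationalization of
  substituent/ring/linker removal; networks built with other dialects
  (e.g. attachment-marked nodes, edge-typed cuts) will differ in node
  granularity.
* Descriptor values depend on the underlying perception toolkit's
  conventions; they are reproducible within this package but not guaranteed
  to match other software to the last decimal.
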