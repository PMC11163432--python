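# Methods

This note documents the models and procedures implemented in
`fragscreen`, the defaults and why they were chosen, what the synthetic
benchmark does and does not emulate, and the numerical conventions that
make runs reproducible.

## The screening problem

Given a protein target and a library of candidate ligands (SMILES), rank
the library so that true binders concentrate at the very top. The
toolkit implements two complementary ranking routes over the same
target-side information — a set of *template pockets*, i.e. binding
pockets from solved protein–ligand complexes whose structure matches the
target — and a meta-route that fuses them:

1. **Similarity route.** Rank candidates by fingerprint similarity to
   the ligands bound in the template pockets. Accurate when the target
   has close template chemistry; unable to generalize beyond it.
2. **Machine-learning route.** Learn, across many targets, which ligand
   fingerprint bits co-occur with which pocket amino-acid compositions
   in true binders, and score new target–ligand pairs from those
   features alone. The template ligands influence only the pocket
   definition, not the score, so novel chemistry can rank highly.
3. **Meta route.** Convert each route's raw score to a predicted
   precision and keep, per ligand, the best one.

## Fingerprints

All hashed schemes share one convention: identifiers are 32-bit FNV-1a
hashes of typed byte serializations, and an identifier sets bit
`id mod L`. Indices are 0-based internally; text dumps render them
1-based. The hash is pinned in code so bit patterns are identical across
runs, platforms and library versions. Cross-toolkit *bit-level* parity
(e.g. with Open Babel or RDKit outputs) is explicitly not promised —
each toolkit has its own internal hash — only structural parity
(counts, collisions, invariances), which the tests verify against an
independent recursive re-derivation and a third-party path enumerator.

* **Morgan / extended-connectivity, radius 2, 2048 bits.** Initial atom
  invariants: (element, degree, attached-H count, formal charge,
  in-ring flag, aromatic flag). Each round hashes an atom's previous
  identifier with the sorted (bond order, neighbor identifier) pairs;
  sorting makes the result independent of atom input order. An atom
  whose environment atom set stops growing keeps its identifier and
  emits no duplicate — this is what makes a single-atom molecule yield
  exactly one bit at any radius.
* **Linear paths (FP2-style), 1024 bits.** All simple paths of 2–7
  atoms, encoded as alternating element symbols and bond-order codes
  (aromatic bonds get their own code so kekulization cannot change
  bits), canonicalized to the lexicographically smaller direction.
  Single atoms contribute nothing.
* **Substructure keys, 881 bits.** Bit *k* is set iff key *k* matches at
  least its threshold count. The packaged table is *synthetic*: the
  genuine external key specification ships with third-party descriptor
  software, so the module generates its own 881-entry table following
  the published section layout and sizes exactly (115 element counts,
  148 ring features, 64 atom pairs, 89 + 44 neighborhoods, 253 simple
  and 168 complex SMARTS). Semantics per key are faithful
  (count-thresholded occurrence); the individual patterns are this
  package's systematic enumeration. Workflows that require the external
  tool's exact bits can ingest its 881-column CSV via
  `fragscreen.io.read_descriptor_table`.

Concatenation order is fixed — keys | paths | Morgan — giving 3953 bits
in full; ablations drop named blocks and the recorded offsets let every
block be recovered from the concatenated vector.

## Target features and template filtering

A candidate template pocket survives iff TM-score > 0.6 (strict) and
aligned fraction ≥ 0.8, optionally also sequence identity ≤ a cutoff
(benchmarking mode, to keep trivially homologous templates out);
survivors are ranked by the upstream pocket rank score and truncated to
75. The 20-dimensional target feature is the mean amino-acid composition
of the accepted pockets, in alphabetical one-letter order. "Mean" is
read as the equal-weight mean of per-pocket compositions — robust to
pocket-size imbalance — with residue-pooled counting available behind a
flag (`pooled=True`); on balanced pockets the two coincide. Non-standard
residue codes are dropped before normalizing; the vector always sums
to 1.

Pairwise sequence identity (for the leave-one-target-out exclusion) is
the identical-column fraction of an optimal global alignment with match
1, mismatch 0, gap open −1, gap extend −0.5; the input pair is ordered
canonically before aligning so the function is exactly symmetric even
under alignment ties.

## Binder scoring

Feature vector: composition (20) ⊕ combined fingerprint (3953 full /
2048 onlyMF / ...), total 3973 in the full configuration. Labels:
1 for actives, 0 for decoys. Training set: all actives plus a seeded
uniform ~10% subsample of decoys, per target (per-target rather than
pooled subsampling so every target contributes negatives; the pooled
variant is switchable). Learner: xgboost regression trees with squared
error, `tree_method="hist"`, single-threaded for bit-reproducibility.
Presets: 3000 or 300 estimators, both depth 6 and learning rate 0.05 —
the deep preset pairs with the full combined features; the shallow one
is the lighter configuration retained for comparison.

Cross-validation is leave-one-target-out with an 80% sequence-identity
exclusion: for each test target, train on all other targets at ≤ 80%
identity, then score the test target's full library. Ranked output
sorts by score descending with ligand-identifier tie-breaking, so ranks
are reproducible even in flat score regions.

A practical note on the presets at desk scale: on the small, cleanly
separable synthetic training sets the squared-error fit converges well
before 300 trees, so the 300- and 3000-tree presets produce predictions
differing only at the 1e-6 level and identical rankings — the acceptance
report's identical metrics for the two presets are expected, not a
collapse of configuration.

## Similarity screening

Template ligands of all accepted pockets are parsed, fingerprinted
(Morgan by default) and deduplicated by SMILES; unparsable records are
skipped with a warning. The candidate score is the maximum Tanimoto
coefficient over the template set (`mean_topk` is available as an
alternative aggregation, and the aggregation point is deliberately
pluggable since the ancestor method's exact pooled-similarity formula is
defined in earlier work). Morgan-only is the default representation:
similarity weights every bit equally, so concatenating weaker schemes
dilutes rather than helps — unlike the ML route, which learns per-bit
relevance.

## Calibration and meta-combination

All cross-validation predictions of one method — every target, actives
and decoys — are pooled, and predicted precision is fit as an isotonic
(monotone non-decreasing) regression of the 0/1 label on the raw score.
Each isotonic block's value is exactly the empirical precision of the
pooled predictions in that score range, the construction is
parameter-free, and the mapping is stored as interpolation breakpoints
(JSON-serializable); out-of-range scores take the boundary value and
outputs are clamped to [0, 1]. A one-feature logistic alternative sits
behind a flag. Similarity and ML scores are calibrated separately since
their scales differ. The meta-screen scores each ligand by the maximum
predicted precision over the methods that scored it, recording the
winning method; with a single method it reduces to the identity.

## Evaluation metrics

* **EF_x** = (actives among the top ⌈x·N⌉ entries / all actives) / x.
  The ceiling guarantees a non-empty selection for any x > 0. With the
  ceiling, the attainable maximum is min(1/x, ⌈xN⌉/(A·x)), which
  reduces to the familiar min(1/x, N/A) when x·N is integral; at the
  synthetic scale (N = 305, top = 4, A = 5) the per-screen EF_1% cap is
  80.
* **ROCEF** = TPR at the first rank where the false-positive fraction
  reaches the given FPR, divided by that FPR; maximum 1/FPR (100 at 1%)
  independent of the active:decoy ratio.
* **AUPR** is average precision (step integration, no linear
  interpolation — interpolation overestimates PR area).

Across targets, metrics aggregate as unweighted means with standard
deviations; targets missing a metric are excluded from that mean with a
reported count.

## Synthetic benchmark

The generator emulates the *shape* of the standard screening
collections — per-target actives, a 60:1 decoy:active ratio (30:1
preset), template pockets with structural scores and bound ligands, a
pairwise target-identity matrix — with a planted signal at the
fingerprint level, which is the only level the screening routes observe.

Targets belong to scaffold families (default 4). Each family has a
random chemical scaffold (9–13 heavy atoms) and a residue-profile
signature (6 boosted amino acids). Per target: pocket residues and the
target sequence are drawn from a noisy copy of the family profile;
template ligands are the family scaffold with 0–2 random substituents;
each active is, with probability `signal_strength`, the scaffold with
1–4 substituents, otherwise a random molecule; decoys are random
molecules of matched size. At `signal_strength = 0` actives are drawn
from exactly the decoy distribution. Random molecules are assembled
atom-by-atom under valence constraints (C/N/O/S, occasional double
bonds, aliphatic rings and benzene seeds), always sanitize-valid and
with exact heavy-atom counts.

Two design points matter for honest testing. First, families are what
make the leave-one-target-out ML check meaningful: the held-out target's
scaffold is still in training via its family partners, so the model can
generalize; without families the ML route would be at chance by
construction. Second, ligand identifiers are assigned from a shuffled
namespace that is blind to the active/decoy split, so the deterministic
identifier tie-breaking in ranked output cannot bias null-signal
enrichment.

What the generator does **not** emulate: property-matched decoys (decoys
here differ from actives by scaffold, not by matched physicochemical
properties — real benchmarks are much harder), binding affinity
structure, assay noise, target-family imbalance, and realistic
protein-sequence homology (identities between generated targets are
~0.15–0.3, so the 80% exclusion never fires; the exclusion logic is
tested separately with constructed matrices). Passing the recovery
checks therefore demonstrates that the pipeline's plumbing, learning and
calibration machinery work end-to-end, not that the method attains any
particular accuracy on real screening collections.

Default problem sizes: the recovery benchmark is 10 targets × (5 actives
+ 300 decoys) and the null benchmark 20 targets, sizes at which the full
pipeline (including two leave-one-target-out sweeps) completes in about
a minute on one CPU while leaving the planted-signal and null statistics
well resolved. The null check uses the exact hypergeometric band for the
mean EF of random rankings (top-⌈xN⌉ active counts convolved across
targets, central 95%).

## Numerical conventions and degenerate inputs

Seeds flow through `numpy.random.default_rng` / `SeedSequence` spawning;
the same seed reproduces a benchmark byte-for-byte. Floats serialize via
`repr` so every TSV round-trips exactly. Unparsable SMILES are skipped
with logged counts everywhere a library is consumed, but a fully
unscoreable library, an empty template-pocket set, a single-class
training pool or calibration pool, a screen without actives (or without
decoys, for ROCEF) are hard errors naming the offending target. Ties in
ranked output are broken by ligand identifier ascending. Model archives
record hyperparameters, seed, ablation and feature layout, and loading
refuses an archive whose recorded layout contradicts its ablation.

## Known limitations

* The packaged 881-key table is a synthetic stand-in (section-faithful,
  pattern-synthetic); exact parity with externally computed descriptor
  tables requires ingesting those tables.
* The similarity route's aggregation defaults to max-Tanimoto; the
  ancestor method's exact pooled formula can be plugged in but is not
  restated here.
* Calibration assumes pooled cross-validation predictions are
  representative of deployment scores; applying a calibration fitted on
  one benchmark to another target distribution shifts precisions.
* The synthetic benchmark's decoys are not property-matched, so absolute
  enrichment values on it are far above what real collections yield.
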