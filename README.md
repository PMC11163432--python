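# fragscreen

Virtual ligand screening (VLS) ranks a large compound library by each
molecule's predicted likelihood of binding a protein target, so that only
the very top of the list needs experimental testing. `fragscreen` is a
toolkit for the *ligand-homology-modeling* family of VLS methods: instead
of docking 3D structures, it works from (a) template binding pockets —
pockets of solved protein–ligand complexes that structurally match the
target — and (b) 1D SMILES-derived fingerprints of the candidate ligands.
It is aimed at computational chemists who want a reproducible,
desk-runnable implementation of this screening stack: the fingerprint
conventions, the pocket-derived target features, the boosted-tree scoring
model, the template-similarity screen, the precision calibration used to
fuse the two, and the standard evaluation metrics.

## What is implemented

**Ligand fingerprints** (`fragscreen.fingerprints`). Three schemes over a
common folding convention (a pinned 32-bit FNV-1a hash; bit index =
identifier mod length; 0-based internally, rendered 1-based in dumps):

* **Morgan / extended-connectivity (MF, ECFP4-style)** — iterative
  neighborhood hashing to radius 2, folded to 2048 bits. Invariant to
  atom input order.
* **Linear-path (FP2-style)** — all simple linear fragments of 2–7
  atoms, read in their lexicographically smaller direction, folded to
  1024 bits; single atoms and rings as such are not indexed.
* **Substructure keys** — an 881-key table (element counts, ring
  features, atom pairs, neighborhoods, SMARTS patterns); bit *k* is set
  iff key *k* occurs at least its threshold count. The packaged table is
  a synthetic enumeration following the published section layout (see
  `fragscreen/pubchem_keys.py`); externally computed 881-column
  descriptor tables can be ingested as a drop-in replacement.

The three blocks concatenate in fixed order (881 + 1024 + 2048 = 3953
bits), with ablation presets `full`, `noFP2`, `noPubChem`, `noMF`,
`onlyMF`.

**Target features** (`fragscreen.pockets`). Candidate template pockets
are filtered by TM-score > 0.6, aligned fraction ≥ 0.8, an optional
sequence-identity cutoff (benchmarking mode), and truncated to the top 75
by upstream rank. The target feature is the 20-dimensional mean
amino-acid composition of the accepted pockets.

**Binder scoring** (`fragscreen.scoring`). A target–ligand pair is
featurized as composition ⊕ combined fingerprint (3973 dimensions in the
full configuration) and scored by gradient-boosted regression trees fit
to 0/1 binder labels (xgboost; presets 3000 or 300 trees, depth 6,
learning rate 0.05). Training uses all actives and a seeded ~10% decoy
subsample per target; leave-one-target-out cross-validation excludes
training targets above 80% sequence identity to the test target.

**Similarity screening** (`fragscreen.similarity`). Candidates are ranked
by the maximum Tanimoto coefficient between their Morgan fingerprint and
the fingerprints of the template ligands bound in the accepted pockets
(aggregation is pluggable: `max` or `mean_topk`).

**Calibration and meta-combination** (`fragscreen.calibration`). Each
method's pooled cross-validation predictions are converted to *predicted
precision* by isotonic regression of the label on the raw score; the
meta-method ranks every ligand by the best predicted precision across
methods.

**Evaluation** (`fragscreen.metrics`). EF_x = (fraction of all actives
recovered in the top ⌈x·N⌉ entries) / x, with random expectation 1;
ROCEF = TPR at a fixed false-positive rate divided by that rate (maximum
100 at 1% FPR, independent of the active:decoy ratio); and AUPR in its
step-integrated average-precision form.

**Synthetic benchmark** (`fragscreen.synthetic`). A generator for
multi-target actives/decoys screens with a planted scaffold signal shared
between actives and template ligands, tunable decoy:active ratio (60:1
default, 30:1 preset) and signal strength, so the whole pipeline is
testable end-to-end without external downloads.

All core operations are also exposed as scikit-learn-style estimators
that compose with sklearn pipelines: `MorganFingerprinter`,
`FP2Fingerprinter`, `PubChemFingerprinter` and `CombinedFingerprinter`
(SMILES → bit-matrix transformers), `BinderScorer` (`fit`/`predict`),
`SimilarityScreener` (`fit`/`screen_library`) and `PrecisionCalibrator`
(`fit`/`transform`).

## Worked example

Generate a small 4-target benchmark (5 actives and 100 decoys per
target, full planted signal), run the template-similarity screen, and
evaluate it:

```bash
fragscreen simulate --targets 4 --actives 5 --decoy-ratio 20 --seed 7 --out bench
fragscreen similarity --benchmark bench --out screens
fragscreen evaluate --screens screens --out metrics.tsv
```

The evaluate step logs `4 targets, mean EF=40.00 AUPR=0.884` and writes
`metrics.tsv`:

```
# mean_aupr	0.883991
# mean_ef	40
# mean_rocef	80
...
target_id	ef	rocef	aupr	n	n_actives
T000	40.0	100.0	1.0	105	5
...
```

Each screen is a ranked TSV; the top of `screens/T000.screen.tsv`:

```
# target_id=T000
rank	ligand_id	score	label	best_template
1	T000_M00090	0.5	1	T000_T0_L1
2	T000_M00033	0.4411764705882353	1	T000_T2_L1
3	T000_M00066	0.358974358974359	0	T000_T3_L0
```

Reading: the two top-ranked ligands are true actives (label 1) whose
Morgan fingerprints have Tanimoto similarity 0.50 and 0.44 to their
best-matching template ligand. A mean EF_1% of 40 on a 105-ligand,
5-active screen means that on average the top-1% slice (2 ligands)
contains 40 × 0.01 × 5 = 2 actives — perfect early enrichment at this
granularity; a random ranking would score EF ≈ 1. The per-target maximum
here is (2/5)/0.01 = 40, so enrichment is at its cap.

`fragscreen screen` (boosted-tree route, with or without a pre-trained
model archive), `fragscreen train`, `fragscreen calibrate` and
`fragscreen combine` cover the remaining pipeline stages; `--help` on
any subcommand documents its options and defaults.

## Scope notes

Protein structure prediction, structural pocket detection and template
ranking are upstream of this package: template pockets arrive as
precomputed metadata (TM-score, aligned fraction, sequence identity,
rank score, pocket residues, bound-ligand SMILES). Reproducing published
benchmark figures on the external DUD-E/DEKOIS2.0 collections requires
those downloads plus a full template-pocket library and is out of scope;
the synthetic benchmark exists precisely to exercise every stage at desk
scale. See `docs/methods.md` for the model details, parameter defaults
and known limitations.
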