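# Methods

This note records the model, the defaults, and the numerical and design
choices behind `funsav`, in the spirit of a statistical software appendix.

## Problem setting and model

A single amino acid variant (SAV) is classified as disease-associated (+1)
or neutral (−1).  The classifier is a two-stage random forest:

1. **First stage** — a forest over features of the variant's local
   environment, computed from the protein's 3D structure, its PSSM profile,
   and a multiple sequence alignment.  Every per-residue feature family is
   replicated over a sliding window of 15 chain positions (V1…V15, variant
   at V8), so the model sees both the mutated residue and its sequence
   neighborhood.
2. **Second stage** — a forest over exactly 7 columns: the first stage's
   disease probability plus the scores of six external sequence predictors
   (SIFT, SNAP, PolyPhen2, PANTHER, nsSNPAnalyzer, PhD-SNP).  External tools
   are consumed as input columns, never re-implemented; tools that emit a
   class call are encoded disease = 1 / neutral = −1.

Random forests default to 500 trees, √p features per split, unlimited depth
— the classical R `randomForest` defaults.  The decision threshold on the
disease probability is 0.5.  Missing feature values are preserved through
encoding and median-imputed only at model-fitting time (medians stored with
the fitted model), keeping the feature matrix an honest record of what was
computable.

### Out-of-fold stacking

First-stage scores used to train the second stage are always produced
out-of-fold (5-fold within the training set).  Feeding the second stage
in-fold scores from a forest fit on the same rows leaks the training labels
(a forest's resubstitution scores are nearly perfect) and teaches the second
stage to over-trust them; the test suite contains a canary asserting the
out-of-fold scores generalize rather than memorize.  Stacked-ensemble
practice varies on this point, so the choice is stated explicitly here:
first-stage inputs to the second stage are always out-of-fold.

## Feature definitions and defaults

| family | parameter | default | rationale |
|---|---|---|---|
| contact network | distance cutoff | 6.5 Å, inclusive | standard residue-contact threshold for center-to-center distances |
| contact network | residue center | heavy-atom centroid | "center" is ambiguous; Cα-only mode exposed for sensitivity checks |
| half-sphere exposure | sphere radius | 13 Å | the customary HSE radius |
| SASA | probe radius | 1.4 Å | water probe |
| SASA | sphere points | 960 | ≤1 % error on an isolated atom (verified against 4π(r+probe)²) |
| H-bonds | energy cutoff | −0.5 kcal/mol | Kabsch–Sander electrostatic criterion E = 0.084·332·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN) |
| window | size | 15 (odd) | centre V8; PSSM block 15×20 = 300 |
| Z-score filter | threshold | Z > 1.0, strict | candidate = "optimal feature candidate" |
| MDGI averaging | repeats | 100 (25 in tests) | importance averages stabilize well before 100 fits |
| stepwise CV | 5-fold × repeats | 10 repeats (100 is the full-fidelity setting) | per-row scores averaged across repeats before thresholding |
| stepwise | improvement ε | 1e-4 | operationalizes "until the MCC no longer increases" in floating point |
| forest | trees / mtry | 500 / √p | R randomForest defaults |

Notes on individual families:

- **Conservation score.**  Shannon entropy (nats) of the PSSM frequency row:
  0 = perfectly conserved, ln 20 = uniform.  Any logarithm base is a
  monotone rescaling and therefore irrelevant to forest-based ranking; nats
  are used throughout the package.
- **PSSM window block.**  The flattened elements are the integer log-odds
  scores (the matrix elements proper); a `matrix="freqs"` switch selects the
  frequency rows instead.  Window positions overhanging the chain are
  zero-padded with explicit `in_range_V*` flags, so the information that a
  position was padded is preserved rather than aliased into zeros.
- **Closeness and status.**  Status S_i is the sum of geodesic distances
  from residue i to every other residue of its connected component;
  closeness is the vertex-count form C_i = (n_comp − 1)/S_i, so
  C_i·S_i = n_comp − 1 holds exactly on every component (a property test
  asserts it on random geometric graphs).  An edge-count variant of this
  identity circulates in the applied literature but breaks the invariant
  and is not used.  Isolated nodes get S = 0, C = 0 by convention.
- **Cyclic coefficient and cocitation** have no networkx implementation and
  are computed from their definitions: the mean of 1/ℓ over the smallest
  cycles through a node and each pair of its neighbors (0 when none), and
  the mean shared-neighbor count with each neighbor.  Hubscore and
  eigenvector centrality coincide on undirected graphs up to scaling; both
  columns are emitted (unit-norm) for interface completeness.
- **SASA** is an in-house Shrake–Rupley sampler (deterministic golden-spiral
  points) because the exposed *surface points* are reused to compute residue
  depth (RD = mean heavy-atom distance to the nearest retained surface
  point; RDa = that of Cα); library SASA implementations do not expose their
  surfaces.  Relative accessibilities are normalized by Gly-X-Gly reference
  maxima computed at runtime from extended tripeptides built by the
  package's own peptide builder — with side chains truncated at Cβ, matching
  the synthetic structures, so the reference is self-consistent rather than
  transplanted from full-side-chain tables.
- **Half-sphere exposure** splits a 13 Å sphere around Cα by the plane
  normal to Cα→Cβ; glycine (or any residue lacking Cβ) uses an ideal
  tetrahedral pseudo-Cβ built from N/CA/C.  CN = HSEAU + HSEAD by
  construction.
- **Hydrogen placement.**  When the amide H is absent (the common case for
  X-ray structures) it is placed 1.01 Å from N along the bisector of the
  N→C(i−1) and N→CA directions.  Classic DSSP instead places H along the
  previous residue's C=O direction; both reproduce the i→i+4 helical ladder
  on the ideal-helix fixture, and the bisector form needs one fewer atom.
  Proline cannot donate and is skipped; donor–acceptor pairs closer than two
  sequence positions are excluded.
- **Backbone virtual angles.**  KAPPA is the vertex angle at Cα(i) between
  the rays to Cα(i−2) and Cα(i+2) (collinear trace → 180°); ALPHA the signed
  Cα(i−1…i+2) torsion in (−180°, 180°]; TCO the cosine between consecutive
  C=O vectors.
- **Coevolution.**  Unweighted counts, pairwise-complete gap deletion, and a
  50 % per-column gap filter (columns failing it yield missing cells, never
  zeros) — the dominant conventions in the MI-coevolution literature; no
  sequence-weighting scheme is applied (left as an extension hook).  Kai is
  the summed Pearson chi-squared statistic of the 20×20 pair-count table
  with zero-expectation cells skipped; no p-value conversion.  The
  pairwise→site reduction is configurable (mean or max over defined
  partners); the default is mean, and which reduction the original design
  used is unverified.
- **Annotation-distance features** (disulfide flag, metal flag, sequence and
  3D distance to the nearest annotated site) are only emitted when an
  annotation table is supplied; with none, all four are missing and the
  pipeline proceeds.  The distance of a residue to the coordinate origin is
  implemented (`distance_to_origin`) but excluded from default feature sets:
  it depends on the crystallographic frame, not on the molecule.
- **Residue identities** are one-hot encoded (20 wild-type + 20 mutant
  columns); index encoding would impose an arbitrary ordinal structure.

## Evaluation

SEN = TP/(TP+FN), SPE = TN/(TN+FP), PRE = TP/(TP+FP), ACC, and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Any metric with a
zero denominator is defined as 0 and flagged, so degenerate CV folds
aggregate cleanly instead of erroring.  AUC is the trapezoidal area under
the ROC curve with tied scores grouped, which equals the normalized
Mann–Whitney U statistic (ties = ½); the test suite asserts exact agreement
with an exhaustive pairwise oracle.  FPR is the universal FP/(FP+TN).

## Synthetic data: what it emulates, and what it does not

The generator produces all pipeline inputs deterministically from a seed:

- **Structures**: full-backbone (N, CA, C, O, Cβ) chains built by NeRF from
  ideal internal coordinates — canonical α-helix (φ −57°, ψ −47°; rise
  ≈ 1.5 Å, ≈ 100°/residue), fully extended, or random coil; lognormal
  B-factors (median ≈ 20 Å², σ_log 0.3).
- **Alignments**: independent Dirichlet(0.5)-profile columns, with planted
  covarying pairs copied through a fixed residue bijection and decoupled
  with probability 2ε (ε = 0: deterministic coupling, MI = column entropy;
  ε = 0.5: fully independent).
- **Labeled datasets**: informative features are class-shifted Gaussians
  with stated effect sizes (mean separation in SD units; default 3 features
  at d = 2.0 among 50 noise features, n = 400, balanced classes); tool
  scores are y·s + N(0, σ) with signal s (0 = pure noise) and optional
  per-column missingness — conditionally independent of the features given
  the label, which is what makes stacking informative.

Passing tests on these fixtures demonstrates the correctness of the
computations and the recoverability of planted signal under the stated
conditions.  They do not demonstrate performance on real proteins: real
side chains, packing heterogeneity, alignment phylogeny, label noise and
the error correlations of real external predictors are all absent by
design.

## Problem sizes used by tests and the acceptance script

Importance averaging uses 25 forest fits and stepwise selection 10 CV
repeats with 100-tree forests (the library defaults remain 100/100/500);
the stacking comparison uses 20 paired seeds at n = 300.  These sizes give
stable pass/fail behavior for the planted-signal checks while keeping a
full run in minutes.

## Known limitations

- Single-chain analysis: no inter-chain contacts, ligand-aware networks or
  quaternary structure; multi-model files use model 1 only; no mmCIF.
- Variant positions are matched in author (PDB) numbering; when a numbered
  residue is absent or its wild type disagrees with the structure, the
  variant is rejected with a mapping report rather than silently shifted.
- Residue depth derives from the sampled solvent-accessible surface, so it
  carries the sampler's resolution (not an analytic surface).
- The MDGI Z-score filter assumes exchangeability of uninformative
  importances; heavily correlated feature blocks (e.g. the PSSM window) can
  share importance mass and individually fall below the threshold.
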