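# funsav

Predicting whether a single amino acid variant (SAV) in a protein is
**disease-associated or neutral**, with a two-stage random-forest classifier
built on sequence, structure and residue-contact-network features.

Most missense-variant predictors work from sequence alone.  When a 3D
structure is available, features of the mutated residue's physical
environment — burial, packing, exposure, backbone geometry, and its position
in the residue-contact graph — carry complementary signal.  `funsav`
implements the full feature-engineering stack for that setting, a two-step
feature-selection procedure, a stacked (two-stage) random-forest model that
fuses the structural classifier with the scores of six external sequence
predictors, and the evaluation harness around it.  A synthetic-data module
generates every input format the pipeline consumes, so the whole package
builds and tests with no downloads.

## What it computes

**Feature families** (per residue, windowed over 15 positions V1…V15 with the
variant at the centre V8):

- *Sequence*: PSSM window block (15×20 = 300 values, `PSSM_V1…PSSM_V300`),
  conservation score `Con = −Σⱼ p_ij ln p_ij` over the PSSM frequency row
  (low = conserved), residue mass change upon mutation, one-hot residue
  identities, and pass-through columns for external per-position predictors
  (PSIPRED, SSpro, DISOPRED, PSIC, TANGO).
- *Structure*: Shrake–Rupley solvent accessibility (absolute + relative, for
  all atoms / side chain / main chain / non-polar / polar side chain),
  half-sphere exposure (CN, HSEAU, HSEBU, HSEAD, HSEBD) and residue/atom
  depth (RD, RDa), backbone virtual angles (KAPPA, ALPHA, TCO),
  Kabsch–Sander hydrogen bonds, B-factor, disulfide/metal flags and
  distances to annotated functional sites.
- *Residue-contact network*: an undirected graph with an edge between
  residues whose centers lie within 6.5 Å; twelve per-node properties —
  degree, closeness, status (S_i = Σⱼ d(i,j), with C_i = (n−1)/S_i),
  hubscore, clustering coefficient, cyclic coefficient, Burt's constraint,
  betweenness, eigenvector centrality, cocitation, coreness, eccentricity.
- *Coevolution*: MI, MIr (MI/joint entropy), MIp (MI − average-product
  correction) and the chi-squared statistic (Kai) over alignment column
  pairs, reduced to per-site scalars.

**Feature selection** is two-step: (1) features are scored by mean decrease
in Gini impurity (MDGI) averaged over repeated forest fits and standardized,
z_i = (x_i − x̄)/σ; features with Z > 1 become candidates; (2) backward
stepwise elimination, accepting the removal that maximizes repeated
stratified 5-fold cross-validated MCC until no removal improves.

**The two-stage model** trains a forest on the selected features, then a
second forest on 7 columns: the first stage's out-of-fold disease
probability plus six external tool scores (SIFT, SNAP, PolyPhen2, PANTHER,
nsSNPAnalyzer, PhD-SNP; class-valued tools encoded disease = 1,
neutral = −1).

## Worked example

Run the full pipeline on a generated fixture:

```bash
funsav synth --out fx --seed 1 --n-residues 30 --n-variants 12
funsav featurize --fixtures fx --out feat --sasa-points 240
funsav select --features feat/features.tsv --out sel --seed 1 \
    --repeats 10 --cv-repeats 2 --trees 100
funsav train --features feat/features.tsv \
    --selected sel/selected_features.txt --out run/model.joblib --seed 1
funsav predict --model run/model.joblib --features feat/features.tsv \
    --out run/scores.tsv
funsav evaluate --scores run/scores.tsv --out run/metrics.json
```

`featurize` prints the matrix shape (`feature matrix 12×945 → feat`: 12
variants, 945 named feature columns per the generated
`feature_manifest.json`), `select` reports the candidate count and the MCC
trajectory of the stepwise elimination (here
`87 candidates → 87 selected (MCC 0.845 → 0.845)` — no removal improved the
cross-validated MCC on this tiny fixture), and `evaluate` prints the metric
report:

```json
{"SEN": 1.0, "SPE": 1.0, "PRE": 1.0, "ACC": 1.0, "MCC": 1.0, "AUC": 1.0}
```

(perfect resubstitution scores on this tiny demonstration fixture — the
model is evaluated on its own 12 training variants; use `funsav.model.
cross_validate` or held-out variants for honest numbers).

In the library API the same steps are
`funsav.featurize_protein` → `funsav.encode_variant` /
`funsav.assemble_matrix` → `funsav.compute_mdgi_zscores` /
`funsav.stepwise_select` → `funsav.train_first_stage` /
`funsav.train_two_stage` → `funsav.metrics_from_scores`.

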