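# Methods

## Problem and model

`malprec` predicts lysine malonylation — a post-translational
modification of lysine side chains implicated in metabolic disease and
cancer — from local sequence context alone. Each candidate site is a
17-residue peptide window `R−8 … R−1 K R+1 … R+8` centered on the
lysine; positions that fall outside the protein are filled with the
dummy residue `X`, so the alphabet has 21 letters
(`ACDEFGHIKLMNPQRSTVWYX`, the fixed column order everywhere).
Prediction is binary classification of windows: modified (label 1)
versus unmodified (label 0).

The pipeline is: **encode → reduce → classify**.

### Feature encodings

Three complementary encodings are concatenated per window
(CKSAAP | one-hot | AAindex, 1764 + 357 + 153 = 2274 columns by
default):

- **One-hot** — per position, a 21-dimensional indicator; 17 × 21 = 357
  dims. Captures raw positional identity.
- **AAindex physicochemical** — per position, nine property scales
  (Hopp–Woods hydrophilicity, Radzicka–Wolfenden mean polarity,
  Zimmerman isoelectric point, McMeekin refractivity,
  Bhaskaran–Ponnuswamy average flexibility, Chothia buried-residue
  volume, electron-ion interaction potential, Bull–Breese transfer free
  energy to surface, Eisenberg consensus hydrophobicity); 17 × 9 = 153
  dims. The scales ship as a plain-text table with accession
  provenance; the `X` column is 0 by default (`x_policy="mean"`
  substitutes the per-property mean).
- **CKSAAP** — composition of k-spaced amino-acid pairs: for each gap
  k, counts of the 21 × 21 = 441 ordered pairs at positions
  (i, i+k+1). The default counts pairs at every window position, with
  partners past the window end reading as `X`, so each k-block sums to
  the window length (a 17-mer at k = 0 yields 17 pairs, the last one
  into padding). The conventional L−k−1 in-window mode is available
  via `pad_beyond_window=False`, and `normalize=True` turns counts into
  per-block relative frequencies. Default gaps k ∈ {0, 1, 2, 3}
  (441 × 4 = 1764 dims), the combination that performed best in the
  encoder sweeps this design follows.

### Reduction

PCA to `d = 100` components (the optimum of the dimension sweep this
design follows; `malprec sweep` reproduces the {50…300} sweep). The fit
uses a full SVD, is deterministic, and canonicalizes each component's
sign (largest-magnitude loading positive). PCA is **always fitted on
training rows only** — per fold during cross-validation — and applied
unchanged to held-out rows, which avoids the information leakage that
fitting on all data would introduce.

**Feature scaling.** The assembled pipeline standardizes columns to
unit variance before PCA (`PipelineConfig.scale=True`). The three
blocks mix counts, indicators and physicochemical values spanning two
orders of magnitude; without scaling the largest-unit AAindex columns
dominate the principal directions and the RBF kernel's distance
geometry, and the classifier degenerates to majority voting. The
`reduction.fit_pca` primitive itself defaults to centering only, so
both behaviours are available and the choice is recorded in model
metadata.

### Classification

RBF-kernel SVM with penalty `c` and kernel width `g`. The default
`g="scale"` resolves to `1/(n_features · Var(X))` at fit time so the
kernel width tracks the feature scale; fixed numeric presets from the
original tuning — (10, 2) for CKSAAP-only, (1.9, 0.07) for the
combined features, (2, 0.1) without PCA — ship in
`classify.SVM_PRESETS`, but they are only meaningful on data prepared
exactly as they were tuned on. `grid_search` re-optimizes (c, g) by
repeated stratified CV accuracy, breaking ties toward the smaller c,
then smaller g.

Four classical baselines mirror the standard comparison setup: KNN
(k = 2, Euclidean), Gaussian naive Bayes, random forest (20 trees) and
a bagged decision-tree ensemble (50 trees — "ensemble of decision
trees" is under-specified in the literature this follows; bagging is
our interpretation). Scores are positively oriented
(decision-function for the SVM, positive-class probability otherwise)
and labels are `score > threshold` for every classifier.

### Evaluation

Confusion-derived metrics Acc, Sen, Spec, PPV, F1 (harmonic mean of Sen
and PPV) and MCC; any 0/0 denominator yields a flagged NaN that is
excluded from averages with an exclusion count. ROC curves sweep every
distinct score as a threshold; AUC is the trapezoidal area, identical
to the Mann–Whitney statistic with ties counted half (asserted to
1e-12 against a pair-counting oracle). Cross-validation is stratified
5-fold, repeated (50 repeats for a production run; tests and the
acceptance script use 1–3 repeats at n = 1000–1200 windows, sizes
chosen so the whole suite runs in well under an hour on one core), with
the reported AUC the mean of per-fold AUCs.

### Dataset assembly

Exact-duplicate peptides are collapsed (first kept; duplicates with
conflicting labels are dropped entirely — a sequence observed both
modified and unmodified cannot train a sequence-only model). Negatives
are down-sampled uniformly to the positive count. The independent
hold-out is a stratified 20% split with per-class banker's rounding;
for a balanced set of 3470 this gives 694 / 2776 (the 695 / 2775 split
sometimes quoted for that dataset size is not reproducible from the
stated 20% rule; we implement the rule, not the quoted count).
Similarity-based redundancy removal (CD-HIT at 40% identity) is an
external preprocessing step: the tools accept its output but do not
reimplement it.

### Enrichment analysis

`positional_enrichment` compares the two classes cell by cell: for each
non-center offset (−8…−1, +1…+8) and each of the 20 amino acids, a
two-sample t-test on the per-window presence indicator, pooled variance
by default (the classic two-sample-logo convention; Welch optional).
Direction is the sign of the frequency difference; significance is raw
p < α = 0.05 (no multiple-testing correction by default, Bonferroni
available). Degenerate cells (both groups constant) are handled
explicitly: equal means → t = 0, p = 1; different constant means →
t = ±∞, p = 0. The padding residue `X` and the invariant center lysine
are not tested.

## Synthetic data generator

The generator emulates the compositional asymmetry reported for real
malonylation data — G/L/A/V enriched around modified lysines, K/E
around unmodified ones — as its planted signal. Each non-center
position is drawn i.i.d. from a background composition re-weighted per
class:

    weight(r | class) = background(r) · (1 + effect_size · boost(r))

with boost 2.0 on the class's enriched residues (so an enriched residue
is 3× over-weighted at the default `effect_size = 1`), uniform
background over the 20 amino acids (a human-proteome-like preset is
included), the center fixed to `K`, and a 10% chance of simulating a
sequence edge by replacing a random-length prefix or suffix with `X`.
These defaults were fixed once by a design-time power analysis: they
give the full pipeline ≈0.90 CV accuracy at 500 windows per side and
per-cell enrichment detection power > 0.99 at 1000 per side, i.e. a
clearly-detectable-but-not-trivial signal; `effect_size = 0` makes the
classes exchangeable and is the null for calibration tests. An
optional pair-coupling mode plants a k-spaced pair preference in
positives only — a signal invisible to positional marginals but
visible to CKSAAP features.

What the generator does **not** emulate: positional dependence of the
composition bias, correlations between positions (outside the optional
pair mode), homology/redundancy structure between windows, realistic
protein length and lysine density distributions, and class imbalance at
genomic scale. Passing tests therefore demonstrate that the pipeline
detects planted compositional signal without leakage and with
calibrated nulls — not that it attains any particular accuracy on real
proteome data.

## Numerical and design notes

- All randomness flows from one integer seed, expanded with
  `numpy.random.SeedSequence` into independent per-stage streams;
  every seeded path is bit-reproducible (asserted end to end).
- Labels: 1 = malonylated in all I/O. (An alternative convention
  assigns the indicator 0 to modified sites; we use the conventional
  positive = 1 throughout.)
- PCA requested dimension is clamped to `min(n_rows − 1, n_features)`
  when a CV fold is smaller than `d`; the dimension used is recorded.
- Non-standard FASTA letters (B, J, O, U, Z, `*`) map to `X` with a
  logged warning; any other character is an error. Non-lysine centers
  warn by default and raise in strict mode.
- Models serialize with a format-version tag and refuse unknown
  versions; PCA projections serialize to JSON (including the scaling
  vector) and round-trip bit-exactly.
- The enrichment logo figure is drawn with matplotlib (letters scaled
  by frequency difference); the TSV table is the primary output.

## Limitations

- Sequence-only features: no PSSM/evolutionary profiles, structural
  descriptors or embeddings.
- The nine AAindex scales are reconstructed from their published
  accessions; independent AAindex exports may differ in rounding.
- The bagged-tree reading of "ensemble of decision trees" and the
  pooled-variance t-test are documented interpretations of
  under-specified conventions.
- Accuracy numbers quoted anywhere in this repository are measured on
  synthetic data and are not comparable to results on curated human
  malonylation datasets.
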