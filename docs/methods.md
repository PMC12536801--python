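# Methods

## Problem and model

The phenotype is binary — `Sporulating` vs `Non-Sporulating` — and the
feature space is fixed by an ordered catalog of 160 sporulation-associated
genes grouped into ten stage/regulon categories (onset and checkpoints,
Spo0A regulon, engulfment, SigF/SigE/SigG/SigK regulons, cortex, coat,
germination). A genome is the 0/1 vector of which catalog genes its
functional annotation contains; a gene counts as present when any
annotation row matches its symbol or an alias (case-insensitively) or one
of its KO identifiers, and multiplicity is ignored. Unannotated genes are
treated as truly absent, which presumes high-quality input genomes; for
incomplete MAGs this biases presence downward, a caveat the dropout model
in the simulator makes testable.

The classifier is stacked generalization with two base learners and a
meta-learner:

1. **Random forest** — 500 trees; the number of features tried per split
   (`mtry`) is tuned over {2, 3, 4}.
2. **RBF SVM** — `K(x, z) = exp(−σ‖x−z‖²)` with σ fixed at 0.0378 (the
   convention in which that constant is meaningful; it equals the `gamma`
   parameterization used by scikit-learn), cost tuned over
   {0.25, 0.5, 1, 2, 4, 8, 16, 32, 64, 128}. The SVM's probabilities come
   from Platt-type sigmoid calibration fit on internal cross-validation
   folds of the training data (`CalibratedClassifierCV(..., ensemble=False)`).
   During the cost grid search AUC is computed from the decision function,
   which ranks identically to the calibrated probabilities at a fraction of
   the cost.
3. **Meta random forest** — consumes exactly two features, the RF and SVM
   probabilities of sporulation; `mtry` tuned over {1, 2}; 500 trees (the
   default of the R random-forest implementation the base forest follows;
   the count is not otherwise pinned down).

All tuning uses stratified 10-fold cross-validation with area under the
ROC curve as the selection metric; ties are broken toward the simpler
setting (smaller `mtry`, `C`, or hidden width). The meta-features are
strictly *out-of-fold*: each training genome's base probabilities come
from fold models that never saw it. Concretely, the held-out-fold
predictions of the winning grid row during base tuning are reused as the
out-of-fold probabilities — identical by construction to a separate
out-of-fold pass over the same folds, and cheaper. For deployment, both
bases are refit on the full training set; a new genome's score is the meta
forest's probability over its two base probabilities, thresholded at 0.5
(`≥` maps to `Sporulating`; configurable in the bundle).

Two further algorithms exist for the model-comparison report: XGBoost
(eta 0.1, depth 6, subsample and column subsample 0.8, at most 100 rounds,
early stopping with patience 10 — early stopping needs a validation set
the method description leaves open, so an internal stratified 20%
carve-out of whatever rows are being fit is used) and a single-hidden-layer MLP
(width tuned over {1, 3, 5, 7, 9} by three repeats of 10-fold CV, LBFGS,
at most 200 iterations; grid and repeat count are package defaults,
exposed as arguments).

## Data partitioning and evaluation

The labeled cohort is split per class with `ceil(0.7 · class size)`
genomes in training (a 68+68 cohort yields 48+48 training, 20+20 test).
Six metrics are reported: accuracy, AUC (Mann–Whitney concordance, ties
half), recall, specificity, precision, F1; 0/0 ratios become an undefined
marker that is excluded from summaries with a logged count rather than
propagated as NaN.

Uncertainty is a non-parametric bootstrap, interpreted as
retrain-on-resample / evaluate-on-fixed-test: each of 300 iterations
resamples the *training* set with replacement (stratified, class counts
preserved, so no resample collapses to one class), retrains the model
under evaluation, and recomputes all six metrics on the untouched test
set; medians and percentile 2.5/97.5 intervals summarize the 300 values.
This is the only reading under which confidence intervals for test-set
quantities like specificity make sense. The five-model comparison report
(`compare_models`) runs this for RF, SVM, XGBoost, MLP and the stack on a
single shared 70/30 split and formats cells as `median (low–high)` in
percent with one decimal, trailing `.0` stripped.

## Shapley attribution and gene selection

Feature importance is Shapley attribution of the model's sporulation
probability with respect to feature presence, estimated by permutation
sampling against a background set (default: the training matrix). Each
sample is a (permutation, background genome) pair; walking the permutation
and switching features from the background value to the explained genome's
value credits each feature with the model-output change it causes.
Antithetic pairs (each permutation and its reverse) reduce variance, and
the *same* sample draws are shared by all explained genomes, which makes
the additivity identity `base + Σφ = f(x)` exact for every genome (the
telescoping sums cancel; `base` is the mean prediction over the drawn
background rows). With `n_samples` below twice the feature count a warning
flags loose estimates. Against exhaustive `2^d`-coalition enumeration on
small models the sampler agrees to ~1e-3 mean absolute error at a 4,000
sample budget (the acceptance suite asserts ≤ 0.02).

A *consensus gene* has positive mean signed contribution in both base
models, ranked by the average of the two mean-absolute contributions. The
explained cohort for this rule is the **predicted spore-formers**: over a
balanced cohort the signed contributions of a truly informative gene
cancel by symmetry (presence pushes spore-formers' probability up, absence
pushes non-spore-formers' down), so "positive predictor" only carries its
intended meaning on the genomes predicted to sporulate. The library
function takes any matrix; the CLI and the acceptance checks pass the
predicted spore-formers. *Core genes* are simpler: catalog genes present
in every member of a genome set, reported with the per-gene presence
histogram and per-stage gene counts per genome.

## Ordination and dispersion

Binary (Jaccard) distance: discordant positions over positions where at
least one genome has the gene; two all-absent genomes are at distance 0 by
convention. PCA is computed on the centered, unscaled 0/1 matrix via SVD;
zero-variance components are dropped, percent variance sums to 100, and
each component's sign is fixed by making its largest-magnitude loading
positive. Dispersion follows the betadisper construction: principal
coordinates of the distance matrix via double centering of squared
distances, keeping axes with negative eigenvalues; each genome's squared
distance to its group centroid is the real-axis part minus the
imaginary-axis part, floored at zero (this matches `vegan::betadisper`
with `type="centroid"` to machine precision, which one test verifies
through Rscript). Group difference in mean dispersion is a one-way ANOVA
F statistic; its p-value comes from permuting group labels over the fixed
distance-to-centroid vector (1,000 permutations by default), with
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`. Recomputing centroids inside
each permutation is a legitimate alternative scheme; the cheaper
fixed-distance scheme is used, and under the null the resulting p-values
are uniform (asserted by a KS check across scaled-down replicates).

## Synthetic data

The generator mirrors the training conditions: 68 sporulating + 68
non-sporulating genomes over the 160-gene catalog; 20 informative genes
present with probability 0.9 in spore-formers and 0.1 in
non-spore-formers; all other genes at 0.2 in both classes; informative
genes chosen stage-block by stage-block so they co-occur like regulons
(within a block each gene copies a shared per-genome latent draw with
probability `sqrt(ρ)`, giving pairwise correlation ≈ ρ, default 0.3);
genome incompleteness as asymmetric dropout flipping 5% of spore-formers'
present genes to absent (assembly loses genes, it never invents them). A
second generator emits near-zero-content genomes (independent presence at
`p_stray = 0.01`) emulating phyla outside the Firmicutes for specificity
testing. Annotation emission writes one emapper-dialect TSV per genome in
which every present gene appears via its symbol or (half the time, when it
has one) via KO only, plus decoy rows foreign to the catalog; parsing and
re-encoding reproduces the source matrix exactly.

What the simulator does *not* model: phylogenetic structure (real Bacilli
and Clostridia share ancestry, so errors correlate within lineages),
class-specific gene repertoires, annotation-transfer errors beyond clean
decoys, and correlated gene loss along genome quality gradients. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of class-conditional presence signal, not field performance
on real MAGs.

## Determinism and numerics

A single user seed fans out to every stochastic component through a
SHA-256 derivation (`derive_seed(seed, stream)`), keeping all derived
seeds below 2³¹. The full pipeline — simulation, annotation emission,
matrix building, training, prediction, attribution — is bitwise
reproducible given a seed, and a saved model bundle (three joblib files
plus `manifest.json` with content checksums) reproduces predictions
bitwise after reload; the manifest also pins the catalog checksum so a
bundle refuses matrices encoded against a different catalog, and
`align_matrix` rejects inputs sharing fewer than half the catalog's genes.
Stratified folds are redrawn (up to 10 attempts) in the degenerate case of
a fold losing a class. Metric formatting rounds to one decimal in percent.

## Problem sizes in the shipped checks

The test suite and acceptance script run at the default study scale
(136-genome cohorts, 160 genes) for training, signal recovery, specificity
(496 genomes) and anti-leakage (20 seeds), and at reduced scale where the
quantity under test is scale-free: the bootstrap/report schema check uses
a 28-genome cohort with 3 iterations, reproducibility uses a 32-genome
cohort, Shapley oracles use ≤ 7 features (exact enumeration is `2^d`), and
the permutation-uniformity check uses 16-genome replicates with 99
permutations. These sizes are the package's own choices for its shipped
checks; every operation accepts full-size inputs.

## Known limitations

* The bundled catalog is a deterministic synthetic placeholder: it carries
  the 25 gene symbols named in the underlying analysis plus filler genes,
  and its KO identifiers are fabricated (K9xxxx). Real use requires a
  curated catalog TSV.
* σ = 0.0378 is treated as a fixed constant of the method; its provenance
  (likely a data-driven kernel-width heuristic in the original
  implementation) is not modeled.
* Only `Preferred_name` and `KEGG_ko` columns of annotation tables are
  consulted; seed-ortholog names and pathway columns are ignored.
* The bootstrap retrains the full model per iteration; at 300 iterations
  for all five models this is minutes-to-hours on one CPU. Scale `n_iter`
  to taste for exploratory work.
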