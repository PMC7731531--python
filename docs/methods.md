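# Methods

This note documents the models and procedures implemented in `smtransfer`,
the parameters that matter, the design decisions taken where the procedure
was genuinely underdetermined, and the limits of what the synthetic
experiments demonstrate.

## Problem setting

Enzyme genes are classified as specialized-metabolism (SM, the minority
positive class) or general-metabolism (GM) from heterogeneous gene features.
Training labels come from pathway databases that are themselves partly
wrong, especially in information-poor species. The pipeline's central claim
is operational: a classifier trained in a well-annotated *source* species on
features shared across species can be used to *filter* the target species'
training labels — removing genes whose annotation contradicts the
cross-species prediction — and retraining on the filtered labels yields a
better target model than either the cross-species model alone or the
unfiltered target model, while removing the same number of genes at random
yields no improvement.

## Synthetic worlds

The generator (`smtransfer.synth`) emulates the statistical structure the
classifier consumes, not transcriptome realism.

**Genes and labels.** Each species has `n_genes` genes. A `df_fraction`
(default 0.05) is dual-function (DF, excluded from training), an
`unannotated_fraction` (default 0.10) carries no observed label, and the
rest are SM with probability `sm_prevalence` (default 0.19, the SM share of
a typical curated enzyme complement). Unannotated genes keep a latent SM/GM
component so genome-wide application can be scored.

**Features.** Shared features (default 30 continuous + 20 binary) carry the
same names in both species; each species additionally has private
continuous features (default 10) absent from the shared list — mirroring
full-feature vs shared-feature model variants. `n_informative_shared`
features (default 40) carry a class effect: continuous features are
unit-variance Gaussians whose SM and GM means differ by `effect_size`
(default 1.0, split ±effect/2 with a random sign per feature); binary
features are Bernoulli(base rate 0.3) with a ±effect/2 log-odds shift.
These are the simplest distributions matching the binary/continuous feature
dichotomy. In the target species only a `cross_species_fidelity` fraction
(default 0.9, exact count) of the informative features keep their effect;
the rest lose it, emulating lineage-specific biology.

**Label noise.** The observed labels of the *target* species are corrupted
independently per gene: true GM observed as SM with probability
`eps_gm_to_sm` (default 0.15) and true SM observed as GM with
`eps_sm_to_gm` (default 0.25). The source species keeps clean labels: the
premise of the transfer design is an information-rich source, and the
filter's validity is tested against a target whose annotations are the
noisy ones. Corruption never touches DF/unannotated genes and preserves
gene count. The default rates are a modeling choice calibrated to the
error proportions seen in curated-benchmark comparisons of real databases
(roughly 14% of benchmark-GM and 21% of benchmark-SM annotations wrong);
no direct measurement of database error rates exists.

**Benchmark subset.** `benchmark_n` (default 88) annotated genes are
sampled without replacement, stratified over true classes
(largest-remainder allocation), and their *true* labels revealed —
emulating a manually curated gold standard that is independent of the
database annotation.

**Seeding.** One experiment-level seed fans out through
`numpy.random.SeedSequence(seed).spawn`; children are consumed in a fixed
documented order (feature layout, source features, target features, target
corruption, benchmark). Identical configs are bit-identical.

## Feature engineering

All operations consume tabular precursors (expression matrix, DE table,
homology/orthogroup tables, coordinates, paralog pairs, domain matrix) and
emit a gene × feature table with per-feature metadata (category, kind,
shared flag).

- **Expression variation** is the unscaled median absolute deviation; the
  procedure's "variation" summary is identified with MAD pipeline-wide.
- **DE breadth** counts contrasts with logFC > 1 (up) or < −1 (down) at
  BH-adjusted *P* < 0.05; BH adjustment is applied per contrast across
  genes (via `statsmodels`), and skipped when the table declares its
  p-values pre-adjusted.
- **Co-expression class features** exclude self-correlation; an empty
  class after self-exclusion yields a missing value, never zero. Partial
  correlation is the rescaled off-diagonal of a Ledoit–Wolf
  shrinkage-regularized precision matrix — well-conditioned when genes
  outnumber samples, reproducing the behaviour of shrinkage partial
  correlation estimators without singularity failures.
- **Module features** come from five clustering methods (k-means, fuzzy
  c-means hardened by argmax membership, complete/average/Ward
  hierarchical); network-based clustering is deliberately not implemented —
  modules enter the model only as 0/1 membership columns, so method
  identity is not load-bearing, and the interface is pluggable.
  Top-module selection ranks by random-forest importance or per-column
  Fisher-exact enrichment, computed on training labels only by default.
- **Genomic clustering** counts same-chromosome neighbours with nearest
  boundary gap ≤ 10 kb AND rank distance ≤ 10 genes (conjunctive reading),
  strand ignored; coordinates are 1-based inclusive, overlap counts as gap
  0. Tandem = paralog at rank distance 1; proximal = rank distance ≤ 10 and
  not adjacent; syntenic/dispersed/pseudogene flags pass through from
  upstream synteny analysis.
- **Missing values**: binary → 0; continuous → median of the column over
  training genes only (leakage-safe).
- **Harmonization**: shared continuous columns are z-scored within each
  species (population SD); binary columns pass through; outputs carry the
  shared columns in identical order and a `harmonized` tag that
  cross-species application verifies. Constant columns become zeros with a
  logged warning.

## Ensemble classifier

With SM a ~0.19 minority, each base learner is trained on a **balanced
draw**: `per_class` genes per class (default 500, capped at the
minority-class training size) sampled without replacement from the training
split (default 10% of annotated genes withheld, stratified). One learner
(random forest by default; an SVM with cross-validated sigmoid calibration
is available) is fitted per draw — 100 draws at full scale. The **SM
score** is the arithmetic mean of the learners' SM-class probabilities; the
signed importance is the mean impurity-decrease importance, given a
positive sign when the feature's mean is higher in SM training genes,
rescaled so the top feature has magnitude 1.

**Hyperparameters** are chosen by exhaustive grid search with stratified
k-fold CV (default 10-fold) on a balanced draw. Fold scoring uses the
learner's native argmax call. This is deliberate: applying F-max
thresholding inside balanced folds would make even a no-skill model score
F = 2/3 (the call-everything-SM rule is always a threshold candidate), so
chance level would no longer be 0.5 and grid points could not be compared
against the random-guess baseline.

**Thresholding.** The final SM/GM call uses the threshold τ maximizing the
F-measure of the rule (score ≥ τ → SM) over the midpoints of adjacent
sorted unique scores plus the two extremes, ties broken toward the smallest
τ. τ is learned on training data only and frozen before any application to
test or unannotated genes. The scores used to select τ are **cross-fitted**
(5 stratified folds, each scored by a small balanced-draw sub-ensemble
trained on the other folds). This choice is load-bearing: when the draw
size equals the minority-class size, every minority gene appears in every
draw, so its out-of-bag-style score degenerates to an in-bag memorized
probability near 1, and a threshold chosen on such scores drifts far above
the score range the ensemble produces on unseen genes (observed to halve
held-out F on cleanly separable training sets). In-bag and out-of-draw
threshold modes remain available as options.

**Evaluation.** `precision_recall_f` reports standard precision, recall and
F (SM positive), plus a class-balanced F in which precision is recomputed
from the true/false-positive *rates* — the F the model would attain on an
evaluation set with equal class sizes. Reported F-measures in comparable
real-data studies are consistent with the balanced convention; experiment
comparisons in this package use the standard F on the stated evaluation
set. For training genes, reported scores are out-of-draw by default (genes
present in every draw fall back to the all-learner mean).

## Transfer, filtering, controls

Cross-species application scores harmonized target features with the source
model and the **source-learned τ**; re-thresholding on target annotations
would partly defeat the filter's independence from them. The disagreement
filter partitions annotated target SM/GM genes into kept vs removed
(GM→SM and SM→GM directions tallied separately); DF/unannotated genes are
untouched. By default the held-out test set is filtered the same way as the
training set (`filter-all`), matching the protocol under which the filtered model is validated on similarly filtered held-out genes;
`filter-train-only` is available and reports state the mode. Random-removal
controls delete exactly the filtered per-class counts uniformly at random
(default 10 repeats, independent, seed-deterministic). A benchmark
label-override option substitutes benchmark true labels for observed ones
before training, reproducing the "annotation-corrected" model variants.

The experiment runner executes: target full-feature model, source
shared-feature model, source-on-target application, target shared-feature
model, filtered retrains (shared and full features), and the controls —
each evaluated on train (out-of-draw), test, and benchmark genes, against
observed labels and (in synthetic worlds) against truth. For filtered
variants under `filter-all`, truth-based metrics on the *original*
unfiltered test set are reported as well, so variants are comparable on a
common gene set.

## Scale choices

Full scale is 100 draws and 10-fold CV. The replica experiment and the
acceptance script run at desk scale chosen once for a single CPU: 2 000
genes per species, 25 draws, 5-fold CV, 50 trees per base learner (1 250
trees per ensemble), single-point hyperparameter grid, and 3 random-removal
repeats per seed with medians pooled across seeds. The test suite uses
smaller worlds (300–700 genes, 4–10 draws) for unit-level properties.

## What the synthetic experiments do and do not show

They show the machinery is correct and the filter is *informed*: on worlds
with planted asymmetric label noise, ~93% of the genes the filter removes
are truly mis-annotated (median over seeds), filtered retraining never hurts
(clean worlds: |ΔF| ≤ 0.02), and random removal of the same counts moves
median F by < 0.03 while the filter's gains are concentrated exactly where
noise was planted (benchmark F in the worked example: 0.74 → 0.92).

They do **not** reproduce the magnitude of real-data gains. With
class-conditional SM↔GM noise, P(observed SM | x) is a monotone transform
of P(true SM | x), so label noise leaves the optimal score *ranking* intact
and mainly perturbs threshold placement and sample efficiency. At the
default generator signal (40 informative features at per-feature effect
1.0, a class Mahalanobis separation near 6) the balanced-draw forest
reaches near-ceiling accuracy against truth even from corrupted labels,
leaving little headroom for the filter on held-out truth-label F. Real
annotation errors are not class-conditionally random — they correlate with
exactly the features the model uses (that is why they were mis-annotated) —
and real class separations are far weaker; both make filtering matter more
in practice than in this idealized generator. The no-free-improvement
behaviour of the random-removal control, and the filter's removal
precision, are the transferable conclusions.

## Known limitations

- Two species only; no multi-source transfer or iterative self-training.
- The generator draws features independently given class; real features are
  strongly correlated (family size, dN/dS, duplication mechanism).
- WGCNA-style module detection is not implemented (interface is pluggable).
- SVM mode has no impurity-based importances; signed importances are
  defined for forests.
- Serialized models store base learners in the host pickle format, which is
  not portable across library versions (hyperparameters, threshold and
  importances are plain text).
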