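# Methods

## The selection procedure

`werfe` selects a compact, discriminative subset of genes from a binary-
labelled expression matrix (m samples × n genes) by combining several
recursive-feature-elimination (RFE) selectors inside one stratified k-fold
cross-validation and letting the selectors *vote*.

**Recursive feature elimination.** One RFE run works on a fixed
train/test split. At each step a classifier is trained on the surviving
genes of the training split; its accuracy on the test split is recorded;
the surviving genes are ranked by a model-derived importance; and the `s`
lowest-ranked genes are removed. When the ranker is the step classifier
itself — the two supported pairings, squared hyperplane coefficients
w_j² of a linear SVM (SVM-RFE) and impurity importances of a random
forest (RF-RFE) — the one trained model per step supplies both the
accuracy and the weights. The loop stops once removing `s` more genes
would empty the set, so the last evaluated subset has between 1 and `s`
genes and every trajectory entry has a defined accuracy. The run's best
subset is the trajectory entry with the highest test accuracy; ties go to
the smaller subset, because a small panel is the goal. Score ties during
elimination are broken by original gene order (stable sort) so runs are
reproducible.

Note that the per-step accuracy is computed on the same held-out fold
that then picks the run's best subset: within a single run the selected
subset is tuned on its test fold. This is inherent to the wrapper design
and is implemented as such, not "fixed"; the ensemble stage mitigates it
by pooling selections across folds, and the final evaluation is a fresh
cross-validation.

**Vote pooling.** The dataset is split into k stratified folds (default
k = 10). In each fold, every selector (default N = 2: SVM-RFE and RF-RFE)
runs on the identical train/test split and contributes its best subset to
a voting pool. A gene's vote t_f is the number of pooled subsets
containing it, so votes range from 0 to k·N; a gene picked by both
selectors in a fold earns two votes that fold. Votes are conserved: their
sum equals the summed sizes of the k·N pooled subsets. Genes are ranked
by descending votes (stable within ties).

**Threshold sweep.** For every integer threshold t₀ in [0, k·N−1] the
candidate subset holds the genes with t_f > t₀ — candidates are nested
and non-increasing in size as t₀ grows. Each nonempty candidate is scored
by stratified k_eval-fold cross-validation (default 10) of an evaluation
classifier on the full dataset restricted to the candidate; empty
candidates get NaN metrics. The final subset is the accuracy-maximizing
candidate; accuracy ties resolve to the larger t₀ (smaller subset), and
an optional `max_genes` cap restricts the choice to candidates at most
that large, encoding the size-versus-accuracy trade-off a user may want
to make by hand. Because the candidates were selected on the same data
that evaluates them, the sweep accuracies are optimistic; the package
therefore also supports held-out validation on replicate data (used by
`scripts/acceptance.py`).

**Incremental search baseline (ISM).** For filter rankers (Fisher score,
ReliefF) the package evaluates nested prefix subsets of the ranking at
sizes θ, θ+step, θ+2·step, … capped at n (defaults θ = 10, step = 10; the
full list is always included so the no-selection baseline is in the
search space) and keeps the most accurate prefix, ties to the smaller.

## Metrics

With class 1 as the positive class (configurable by relabelling):

    Sen = TP/(TP+FN)·100,  Spe = TN/(TN+FP)·100,
    Acc = (TP+TN)/(TP+FP+FN+TN)·100

A degenerate denominator (single-class truth) yields NaN, not an error.
Cross-validated metrics pool the out-of-fold predictions into one
confusion matrix. The ROC curve sweeps the unique score thresholds (tied
scores collapse into one step) on pooled out-of-fold continuous scores —
the SVM margin or the forest's class-1 probability — and AUC is the
trapezoid area, equal to the probability that a random positive outscores
a random negative with ties counted ½ (asserted against a brute-force
pairwise oracle in the tests).

## Rankers

* **SVM weights** — squared coefficients of a linear-kernel soft-margin
  SVM (penalty C, default 1.0). Features are standardized (zero mean,
  unit variance, parameters learned on the training split only) by
  default, since raw expression ranges otherwise dominate the margin.
  Scores are invariant to per-gene affine rescaling exactly when
  standardization is on.
* **Random-forest importances** — impurity-based importances of a seeded
  forest (default 500 trees). Deterministic given the seed; equivariant
  under gene permutation only in expectation, because tree randomness
  depends on column order.
* **Fisher score** — (n₀(μ₀−μ)² + n₁(μ₁−μ)²)/(n₀σ₀² + n₁σ₁² + ε) per
  gene with population class variances and ε = 1e−12 guarding genes that
  are constant within both classes.
* **ReliefF** — features min-max scaled to [0,1]; for each probe sample
  the weight of a gene moves down by its mean absolute difference to the
  k nearest same-class neighbours and up by the mean difference to the k
  nearest other-class neighbours (Manhattan distance; with two classes
  the class-prior reweighting of misses is identically 1). All samples
  are probes by default, which makes the weights deterministic;
  `n_probes` subsamples probes for large m.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| k | 10 | selection CV folds; every selector sees the same splits |
| N (selectors) | 2 (SVM-RFE, RF-RFE) | ensemble width; votes span [0, k·N] |
| s | 1 if n ≤ 500, else ⌈n/100⌉ | genes removed per RFE step; the large-n rule bounds a run at ~100 refits |
| C | 1.0 | SVM penalty |
| n_trees | 500 | forest size |
| k_eval | 10 | folds of the candidate-evaluation CV |
| θ, step | 10, 10 | ISM prefix grid |
| max_genes | none | optional cap on the final subset size |

Fold assignment and every learner seed derive deterministically from one
master seed (children generated via seed sequences, kept below 2³¹), so a
fitted run is reproducible byte for byte.

## Synthetic data

The generator emulates the shapes of public benchmark panels
(presets: 144×70, 300×22, 116×1000). Labels are a fixed count
round(m·class_balance) of positives in seeded shuffled order — a
deterministic count rather than a Bernoulli draw, so both classes are
always present at any m. Informative genes are Normal(±effect/2, 1) by
class (optionally equicorrelated as a block); noise genes are
Normal(0, 1) regardless of class. The generator keeps two random streams:
a *structure* stream fixing which columns are informative and a *noise*
stream for labels and values; `replicate(spec, noise_seed)` redraws only
the noise, so a subset selected on one draw can be validated on a fresh
draw with the same planted truth.

What the generator does **not** emulate: heavy-tailed or log-normal
intensity distributions, probe and batch effects, gene–gene correlation
outside the planted block, class-dependent variance. Passing tests on
this model therefore demonstrate that the machinery recovers a planted
mean-shift signal against Gaussian noise at realistic m/n ratios — not
that it handles microarray artefacts; real data should be normalized
upstream.

## Numerical choices and degenerate inputs

* All score-based orderings use stable sorts; ties preserve input order.
* A test fold with a single class still yields a defined accuracy
  (sensitivity or specificity is NaN and a warning is logged).
* Loaders reject missing values by default; `impute_missing` fills
  per-gene means. Malformed cells, duplicate gene ids, non-binary or
  single-class labels are hard errors naming the offending cell.
* Matrices are written at repr precision and parsed with round-trip float
  precision, so write→read is bit-exact.
* Constant genes: zero SVM weight, zero Fisher between-class scatter
  (ε-guarded denominator), zero ReliefF contribution (zero-span features
  are scaled to 0).

## Problem sizes used in the shipped analyses

The planted-recovery analysis and `scripts/acceptance.py` run the
144×70 preset with 5 informative genes at effect size 2, k = k_eval = 10,
and desk-scale selector settings s = 5 and n_trees = 100 — on a 70-gene
panel an elimination step of 5 still gives a 14-point trajectory per fold
while keeping a full multi-seed study to a few minutes on one CPU. The
library defaults (s per the table above, 500 trees) are unchanged.

## Known limitations

* Binary classification only; multi-class elimination is out of scope.
* The sweep's accuracy estimates reuse the selection data (documented
  above); treat them as model selection, not as an unbiased performance
  estimate — use replicate or external validation for that.
* RF-based results depend on the seed; only the full seeded pipeline is
  reproducible, not individual forests across column permutations.
* No built-in normalization or batch correction; inputs are taken as
  given.
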