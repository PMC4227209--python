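# Methods

`ghstox` builds three-class acute-oral-toxicity classification models from
chemical descriptor tables. This note records the statistical procedure, the
conventions adopted where more than one reasonable choice existed, and what
the synthetic benchmark does and does not establish.

## Classification scheme

Rat oral LD50 (mg/kg) is discretized into the GHS-derived classes
I (LD50 ≤ 300), II (300 < LD50 ≤ 2000) and III (LD50 > 2000), with
boundaries inclusive on the more toxic side: a dose of exactly 300 mg/kg is
class I. Units are mg/kg body weight for an acute (single-dose) endpoint.
Classes are ordered I < II < III, and the mapping is a monotone step
function of dose.

## Descriptor-reduction cascade

Descriptor matrices from batch descriptor generators carry heavy
redundancy. The cascade runs in a fixed order, each stage emitting a
machine-readable report:

1. **Missing-value filter** — any column with one or more missing entries is
   discarded. Missing cells are not imputed; an incompletely computed
   descriptor is treated as unreliable.
2. **Constant filter** — columns with a single distinct value.
3. **Near-constant filter** — columns identical in all but at most one row.
   This "one deviant object" convention is the common one in descriptor
   software; a frequency-based alternative (e.g. 95 % modal frequency) would
   remove more columns and is not used.
4. **Correlation filter** (threshold 0.95) — for each pair with Pearson
   |r| > 0.95, processed in descending |r|, the member with the larger mean
   absolute correlation against all other input columns is removed; ties
   remove the larger column index. The mean-|r| criterion is computed once
   on the input columns and not updated after removals, which makes the
   outcome deterministic and independent of column naming. An O(p²) audit
   confirms no surviving pair exceeds the threshold. Pearson correlation is
   scale-invariant, so filtering raw columns equals filtering autoscaled
   ones. |r| (not signed r) is used: an anti-correlated duplicate is as
   redundant as a correlated one.
5. **PCA-loading filter** (10 components, threshold 0.06) — after
   autoscaling, a column is kept iff its maximum absolute loading across the
   leading components is strictly greater than the threshold. The max across
   components (rather than a per-component rule) is used so that a
   descriptor strongly tied to *any* retained direction of variance
   survives.

Each filter is idempotent, and the stage reports partition the removed
columns.

## Outlier flagging

Rows are scored by a Hotelling-type squared distance in PCA score space:
T²ᵢ = Σ_c t²ᵢ_c / λ_c over the leading 10 components, compared against the
chi-square upper-α quantile (α = 0.025 by default). This is a flagging
rule only — removal is a separate, explicit pipeline step
(`remove_flagged_outliers`), so a user can inspect the flags first. The
chi-square reference is an approximation for in-sample scores; for a few
hundred rows it runs slightly conservative. Degenerate inputs (no column
variance) flag nothing.

## k-nearest-neighbor classifier

Euclidean distance, majority vote. Descriptors are autoscaled with
statistics from the training rows only; held-out rows are scaled with the
training parameters before distances are computed, so all descriptors
contribute comparably. Ties are deterministic: among vote-tied classes the
class of the nearest neighbor belonging to a tied class wins, and exact
distance ties between training rows resolve to the lower row index.

Fitting (resubstitution) predictions exclude the query row itself; with
k = 1 this is what keeps the fitting non-error rate informative rather than
trivially perfect.

k is selected over a default grid 1..10 by 5-fold cross-validation,
maximizing the cross-validated non-error rate with ties going to the
smallest k. The default fold scheme is venetian blinds (row i → fold
i mod 5), the deterministic convention common in chemometrics; a seeded
random scheme is also available.

## Performance metrics

All figures derive from the G×G confusion matrix (rows = true class):

- sensitivity_g = C_gg / row_g,
- specificity_g = (non-g objects not assigned to g) / (non-g objects),
- precision_g = C_gg / col_g, reported as undefined (not 0) when nothing is
  assigned to g and excluded from aggregates,
- **NER** = arithmetic mean of the per-class sensitivities, **ER** = 1 − NER.

NER is the chemometric *non-error rate* (balanced accuracy), not overall
accuracy: duplicating every member of one class leaves it unchanged, so a
dominant class cannot mask failure on a rare one. Published model tables
computed with other software sometimes report NER values that do not equal
the mean of their printed sensitivities; this package always reports the
standard definition above.

## GA descriptor selection

Wrapper selection over binary inclusion vectors. Fitness of a chromosome is
the cross-validated NER of a k-NN model (fixed k = 1 during selection, 5
venetian folds) on the selected columns — deterministic given the folds, so
selection noise comes only from the search, not the evaluation.

Search is a steady-state GA: population 20, tournament selection of size 2,
uniform crossover applied with probability 0.5, per-gene bit-flip mutation
0.01, and implicit elitism (a child only replaces the current worst member,
and only when strictly better). Initial chromosomes switch each gene on
with probability 5/p (≈5 descriptors expected); chromosome size is repaired
into [1, 30]. Evaluations count *distinct* fitness calls — previously seen
chromosomes are served from a cache without consuming budget. The default
budget is 100 evaluations.

The population is deliberately small relative to that budget:
initialization costs one evaluation per member, so a population of 50 would
spend half the budget before any selection occurs, leaving ~50 steady-state
steps. With 20 members, 80 of the 100 evaluations drive actual evolution,
which measurably improves recovery of planted informative descriptors on
the synthetic benchmark while keeping enough diversity for uniform
crossover to recombine distinct partial solutions.

**Budget calibration by y-scrambling.** A batch of runs on the real labels
(default 20) is compared with a batch on per-run permuted labels (default
20): "scrambling" permutes the response vector once at run start,
destroying the descriptor–class link while preserving class sizes. The
mean best-so-far fitness curves are aligned, and the evaluation count with
the largest real-minus-scrambled gap is reported as the recommended budget
— past that point additional search mostly fits noise. Row-order shuffling
would be a no-op for k-NN; response permutation is the meaningful
operation.

**Finalization.** The best chromosome across the real runs wins (ties →
fewer descriptors, then lexicographic order); k is then re-selected by
cross-validation on the chosen subset and the final model is fit on the
full training set. Per-run seeds are base_seed + run index, so any single
run can be reproduced in isolation.

## Stratified split

Per class g with n_g members, the training set receives
floor(0.8 · n_g) members drawn uniformly under the given seed; the rest go
to the test set. The floor convention is the one consistent with splitting
class sizes (103, 171, 162) into train (82, 136, 129) and test
(21, 35, 33). Counts are seed-invariant; membership is not.

## Synthetic benchmark

The generator emulates the data landscape this pipeline targets: a few
hundred chemicals against ~1000 machine-computed descriptors. Defaults:
436 chemicals, 10 informative columns, 960 noise columns, 20 near-duplicate
columns (|r| ≥ 0.96 with their source), 5 constant and 5 near-constant
columns, missing cells at 2 % confined to ~5 % of the noise columns
("fragile" columns, so the missing-value filter never destroys testable
structure), 5 outlier rows, and a 103:171:162 class split.

The response is generated on log10(LD50) — toxic doses span orders of
magnitude — as a linear model Σ β_j x_j + ε with ε ~ N(0,1) and
|β_j| = effect_size (default 1, random signs). The latent score is mapped
affinely onto the log-dose scale so that its empirical quantiles land
exactly on the 300/2000 mg/kg cuts, making the realized class counts match
the target fractions exactly; every generated LD50 therefore re-derives its
class through the ordinary discretization rule.

Outlier rows are displaced by 10 column-SD along a random direction in the
informative+noise space *before* duplicate columns are derived, so an
outlying chemical is outlying coherently in a descriptor and its
near-duplicate, as a structurally extreme molecule would be.

**What the benchmark does not show.** Columns are (near-)independent
Gaussians apart from the planted structure; real descriptor blocks have
heavy inter-block correlation, discrete and skewed marginals, and
non-linear structure–activity relationships. A random-direction outlier
displacement spread over ~1000 columns projects only weakly onto the
leading principal components, so planted outliers are a hard target for
score-space flagging — outlier recall is reported, not asserted. Passing
the recovery tests shows the machinery is correct and able to find planted
linear signal at realistic sizes; it does not certify predictive
performance on real chemistry.

## Numerical choices

- PCA is SVD-based on the autoscaled matrix; explained fractions are shares
  of total variance, so a full decomposition sums to 1. Sign convention:
  the largest-|loading| entry of each component is positive, making scores
  and loadings deterministic across platforms.
- Correlation-loading plots rescale loadings by sqrt(component variance), so
  a variable fully explained by the two plotted components lies on the unit
  circle; the 100 % and 50 % explained-variance circles have radii 1 and
  sqrt(0.5).
- Autoscaling uses the n−1 standard deviation and refuses zero-variance
  columns (inside k-NN cross-validation, a fold-constant column gets scale
  1 and contributes nothing to distances rather than aborting the fold).
- One global pipeline seed expands through a seed sequence into independent
  per-stage seeds (split, GA, synthetic), keeping every stage individually
  reproducible; identical config + seed gives byte-identical JSON reports.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script simulations run at desk scale, chosen
to exercise every code path at the generator's realistic shape: the
end-to-end benchmark at the full default 436 × 1000 with the default GA
batch (20 real + 20 scrambled runs × 100 evaluations), and the recovery
study at 300 chemicals × 200 descriptors with 5 informative columns over
ten generator seeds.

## Known limitations

- The correlation filter's one-pass mean-|r| criterion can differ from a
  recompute-after-each-removal variant on pathological inputs; both satisfy
  the no-pair-above-threshold post-condition.
- The GA is a single-population steady-state search; with the default
  100-evaluation budget it reliably enriches planted signal but does not
  guarantee the globally best subset.
- Chi-square outlier cutoffs are approximate for in-sample PCA scores.
- Structure curation (salt/mixture and duplicate removal, optional
  diazo/guanidine patterns) applies only when SMILES are supplied and does
  not attempt stereochemistry-aware canonicalization.
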