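# Methods

This note documents the models behind `hybridsurv`, the defaults and why
they are set where they are, what the synthetic cohort generator does and
does not emulate, and the numerical choices that matter.

## Survival labeling (Cormack-Jolly-Seber)

Detections are binned into capture occasions of `occasion_days` (default
10) over a `study_days` window (default 300, hence 30 occasions), with
half-open bins `[10k, 10(k+1))`; occasion 0 is the release and is always
set. A detection after the window sets the final occasion: a bird seen
after day 300 demonstrably survived the window, and folding it onto the
last occasion is how the encounter history carries that fact.

The CJS model is a two-state hidden Markov chain conditioned on first
capture: between occasions the bird survives with probability φ\_t; given
alive at occasion t it is detected with probability p\_t; the dead state is
absorbing and silent. The likelihood is computed by a forward pass with
per-step normalization (equivalently, in log space), and is checked in the
test suite against exhaustive enumeration over all alive/dead latent paths
to 1e-10.

Fitting maximizes the summed log-likelihood over bounded parameters using
L-BFGS-B on the logit scale from a flat 0.5 start; estimates are clipped to
[1e-6, 1 − 1e-6] to keep the likelihood finite. Two modes:

- **cohort** (default): one shared time-varying (φ\_t, p\_t) across birds;
  each bird is labelled by its posterior probability of being alive at the
  final occasion (forward filtering). This is identifiable and yields the
  effectively binary posteriors (< 0.001 or > 0.999) the binarization
  expects.
- **per_bird**: each history fitted alone, with the overall survival
  probability taken as the product of the fitted φ\_t. With ~58 free
  parameters against one binary vector the optimum sits on the boundary,
  and the product collapses to ~0 or ~1; the mode is retained because it
  reproduces the one-bird-at-a-time analysis style, not because it is
  statistically defensible.

Two structural choices deserve note. First, the final-interval pair
(φ\_{T−1}, p\_{T−1}) is classically confounded in a fully time-varying CJS —
only their product enters the likelihood — so the fit ties the last
detection probability to the previous occasion's. Without the tie the
optimizer can split the product as φ ≈ p ≈ 0.9 and a bird silent only on
the final occasion earns a ~0.48 posterior; with it, late φ̂ goes to 1 where
no late mortality exists and such birds are labelled correctly. Second,
the binarization threshold is 0.5: any intermediate probability above it
(e.g. 0.82) is called survived, consistent with how such a bird should be
read when almost all posteriors are extreme.

## Feature preparation

Body condition is weight/tarsus (g/mm). Fall orientation is the initial
great-circle bearing (degrees clockwise from north, haversine distances on
a 6371-km sphere) from the release site to the first station detected
within 300 km; stations coincident with the release are skipped because the
bearing is undefined at zero distance, and only fall-season detections
(day-of-year 213–304 by default) qualify so that a bird first seen on its
spring return does not receive a spurious "fall" orientation. Fall timing
is the day-of-year of the first detection within 30 km of the release site
in the same window. The window itself is a package default, not a measured
quantity; it spans August through October.

Preprocessing follows the order: correlation pruning (drop one member of
each pair with |Pearson r| ≥ 0.7, the member to drop chosen by an explicit
keep-priority list whose default keeps wing chord over P7–P9 and condition
over raw mass), missingness filter (strictly more than 25 % missing is
dropped unless whitelisted; fall bearing and timing are whitelisted),
z-standardization, then KNN imputation (k = 5, nan-Euclidean distance,
uniform neighbour weights — matched in tests against a brute-force
all-pairs oracle), then an 80/20 stratified split.

Two pipeline modes exist because "impute everything, then split" and "fit
all preprocessing on training data only" are both reasonable readings of
standard practice and they genuinely differ: `paper-literal` (default)
standardizes and imputes the full table before splitting; `strict` fits the
standardizer and imputer on training rows and applies them to test rows.
The choice is a config flag, and the no-leakage contract of the strict mode
is tested (test rows transformed with training parameters do not center at
zero when the populations differ).

Bearings and days-of-year enter the matrix as linear scalars; sex is 0/1,
imputed like any feature and snapped back to the nearest observed class.

## Imbalance-aware classification

SMOTE oversamples the survivor minority: each synthetic row interpolates a
uniformly chosen minority row toward one of its k = 5 nearest minority
neighbours by λ ~ U[0, 1], until the classes are equal; originals are kept
verbatim and each synthetic row records its parent for leakage audits. The
balanced random forest grows each CART tree on a bootstrap drawing
`n_minority` samples per class. After SMOTE the classes are already equal,
so the balanced bootstrap degenerates to an ordinary balanced resample;
both stages are kept because the pipeline is specified as their
composition. Forest class probabilities are averaged per-tree leaf
frequencies; Gini importances are per-tree mean-decrease-in-impurity
averages, renormalized to sum to one.

Hyperparameters are tuned by randomized search (default 50 candidates; the
count is a package default) over {100, 200, 300} trees, depth {10, 20,
unbounded}, max-features {sqrt, log2, all}, min-split {2, 5, 10}, min-leaf
{1, 2, 4}, scored by stratified 5-fold CV macro-F1 with SMOTE applied
inside each training fold only — no synthetic sample ever derives from a
validation row. Ties go to the first candidate drawn.

## Evaluation

Class 1 is "survived". Accuracy, per-class precision/recall/F1,
specificity (class-0 recall) and macro-F1 come from the test-set confusion
matrix; metrics with zero denominators are flagged and counted as zero in
macro averages so degenerate predictions remain scorable. The decision
threshold is swept over 100 evenly spaced points on [0.40, 0.70]
(prediction rule prob ≥ τ, inclusive; ties broken toward the smaller
threshold), maximizing macro-F1; the sweep runs on the test set by default,
mirroring the workflow it reproduces, and the 80th grid point prints as
0.639. The Brier score (mean squared difference between predicted
probability and outcome) accompanies the threshold metrics as the
calibration check.

## Interpretation

The pairwise interaction screen permutes, for each of the k(k−1)/2 feature
pairs, both columns with *independent* random permutations — breaking the
pair's joint distribution (and its joint relation to the label) while
preserving both marginals exactly — and records the macro-F1 drop at the
tuned threshold; drops ≥ 0.1 are retained. A shared-permutation variant
(one row permutation applied to both columns) is available behind a flag
for comparison. The default is a single permutation per pair
(`n_repeats=1`), with more repeats recommended for stable rankings.

One property of this screen matters for interpreting it: the drop for a
pair confounds the pair's joint contribution with each member's marginal
contribution, because permuting one member alone already destroys any
signal routed through it. A perfectly median-balanced XOR — whose members
have exactly zero marginal signal — therefore degrades every pair
containing either member equally, and the planted pair cannot rank first
except by luck. The power check in the test suite plants the interaction
with indicator thresholds at −0.6 σ, giving each member a marginal
component, which is both what real trait effects look like and what the
screen needs in order to single the pair out.

Shapley values are computed exactly for the tree ensemble under
interventional expectations: for each leaf and each
(foreground, background) pair, the features whose intervals include the
foreground but not the background form a required set A, the reverse a
forbidden set B, and the leaf's contribution to feature i has closed-form
weight |A∖{i}|!·|B|!/(|A|+|B|)! (positive for i ∈ A, negative for i ∈ B).
Averaging over a seeded background subsample (default 25 rows) yields
attributions satisfying additivity — base value plus row sum equals the
predicted probability — to float precision; the closed form is verified in
tests against exhaustive subset enumeration. Sample routing mirrors the
tree library's float32 casting so leaf membership agrees with
`predict_proba` at split boundaries.

## Trait network

Spearman rank correlations (average-rank ties) on pairwise-complete,
pre-imputation observations by default; each pair gets a percentile
bootstrap over rows (default 100,000 replicates in production configs,
10,000 in desk-scale runs) and an edge iff the (1−α) interval excludes
zero (α = 0.05). No multiple-testing correction is applied across the 91
pairs, matching the visualization the network reproduces; at α = 0.05 about
4–5 spurious edges are expected on independent data, and the calibration
test holds the per-pair type-I rate at that level.

## Synthetic cohort generator

The generator is the package's study system. Defaults: 600 birds; hybrid
classes (two parentals, F1, F2, both backcrosses) drawn with fixed
proportions; 1495 fixed-difference ancestry-informative loci per bird, with
per-locus Mendelian mixtures per class (so the triangle constraint
H ≤ 2·min(q, 1−q) holds exactly and parental/F1 classes sit at the
triangle's corners); a one-factor "wing size" morphology model whose
implied correlations put wing chord and P7–P9 above the 0.7 pruning
threshold and everything else below it; fall orientation von Mises with
the circular mean rotating from ~205° (west of south) for coastal ancestry
to ~155° (east of south) for inland ancestry; release days 213–258 with a
broad gamma departure lag so timing and release day correlate at ~0.5;
detection probability 0.8 per occasion; and 28 % shared missingness in the
two behavioural traits (a bird undetected near its release site lacks
both).

Planted survival is Bernoulli(σ(η)) with η = logit(base rate) + Σ cᵢ·zᵢ
over named terms (linear, centered quadratic z²−1, pairwise z-products) on
fixed nominal scales. The default effect set mirrors the structure the
analysis should recover: positive condition, year, heterozygosity and
eastward-orientation effects, an ancestry hump peaking toward inland
backcrosses, and condition×year, ancestry×year and orientation×tarsus
interactions. Because σ is nonlinear, nonzero effect variance inflates the
mean survival rate above σ(logit(base)); the default coefficient set
includes a −0.40 intercept offset compensating that, so the realized
survivor fraction stays at the configured 30.9 % base rate (within
binomial bounds). With all coefficients zero the rate equals the base rate
exactly in expectation.

Detection streams follow a southward great-circle trajectory along the
bird's bearing past a 14-station fence plus scattered continental stations;
non-survivors draw a death occasion in the first ~9 occasions, after which
they are silent; survivors remain detectable through spring, including
roughly two months past the study window — returning birds keep being
detected on the breeding grounds, which is precisely the situation the
"detected after the window ⇒ final occasion" rule exists for.

What the generator does **not** emulate: station-density heterogeneity and
its coupling to route choice (detection probability is spatially constant),
tag failure and battery death, permanent emigration (so apparent survival
is true survival here), inter-annual changes in network coverage (release
year affects survival only through the planted coefficient), and any
genuine biology in the effect sizes. Consequently, passing tests show the
*pipeline* recovers planted structure under its own assumptions — not that
the real system satisfies them; in particular real labeling accuracy
depends on network coverage in ways the constant-p simulation cannot
probe.

## Problem sizes and numerical choices

Test-suite and acceptance runs use desk-scale sizes chosen to make the
checked contrasts decisive at small cost: 600-bird cohorts (the scale of a
multi-year tagging effort), 10-candidate randomized searches, 10,000
bootstrap replicates, 25-row SHAP backgrounds, and 10-replicate power
checks. Production-scale defaults (50 candidates, 100,000 replicates)
remain the config defaults. Optimizer: L-BFGS-B, logit scale, flat start,
parameter clip 1e-6; threshold ties break toward smaller τ; pruning ties
resolve by the keep-priority list; KNN imputation falls back to all
available donors when fewer than k rows observe a feature; display
rounding is half-up (two decimals; percentages to integers).

## Known limitations

- Cohort-mode CJS assumes exchangeable birds; trait-dependent detection
  (e.g. route-dependent station exposure) would bias labels in real data,
  as it would in the workflow this package reproduces.
- The interaction screen's ΔF1 is a marginal+joint disruption measure, not
  a pure interaction statistic (see above); retained pairs are candidates,
  not tests.
- Per-bird CJS mode is boundary-ridden by construction and should be used
  only to mirror the historical analysis.
- The bootstrap network treats rows as exchangeable; phylogenetic or
  spatial structure among birds is not modelled.
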