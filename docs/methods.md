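# Methods

This note documents the models and procedures implemented in `efsubtype`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not establish about real data.

## Similarity network

Subtyping operates on a person-by-person (Q-mode) correlation network.
Inputs are six questionnaire subscale scores per child. Preprocessing:

* **Validity filter.** Rows flagged for a possibly overly negative
  response style can be excluded (`filter_validity`); both variants of the
  analysis are supported because a high negative-impression score may
  reflect either rater bias or genuinely severe problems.
* **Age residualization.** Each scale is regressed on age in months by
  ordinary least squares over the whole retained sample and replaced by its
  residual. A linear model is the simplest choice consistent with a
  monotone age trend over the 5–18-year range; no interaction or spline
  terms are fit.
* **Standardization.** Residual columns are z-scored across children
  (mean 0, sd 1, denominator n). Without this, scales with larger residual
  variance would dominate every child-pair correlation. Degenerate inputs
  (constant scale, fewer than 3 children, perfect age fit) raise errors
  naming the offending column.

The network weight is the Pearson correlation between two children's
six-score profiles (Spearman available); the diagonal is zeroed and the
full signed matrix retained. No thresholding or sparsification is applied:
negative correlations carry real information ("these two children have
opposite profiles") and the signed quality index is designed to use them.
Six points per profile make individual edges noisy; the procedure relies
on the community structure of all ~n²/2 edges, not on any single edge.

## Signed modularity and its optimization

For a partition c of a signed network W, split W into the positive part
W⁺ and the magnitude of the negative part W⁻, with strengths s±ᵢ = Σⱼ w±ᵢⱼ
and totals v± = Σᵢⱼ w±ᵢⱼ. Each part has a classic modularity

Q± = (1/v±) Σᵢⱼ (w±ᵢⱼ − s±ᵢ s±ⱼ / v±) δ(cᵢ, cⱼ),

defined as 0 when v± = 0, and the signed quality index is the asymmetric
combination

Q\* = Q⁺ − (v⁻ / (v⁺ + v⁻)) Q⁻.

Positive weight dominates: moving concentrated positive weight inside
communities is always rewarded, while negative weight inside a community
is penalized with leverage that shrinks as the network becomes mostly
positive. Implementation detail: Q\* is evaluated as the within-community
sum of a single signed modularity matrix M = B⁺/v⁺ − (v⁻/(v⁺+v⁻))·B⁻/v⁻,
which makes the Louvain gain computation and graph aggregation exact and
cheap.

**Louvain.** Two phases are iterated to a fixed point: local moving (each
node, in seed-shuffled order, moves to the community with the largest
positive Q\* gain; ties break to the lowest community index; gain
tolerance 1e-12) and aggregation (communities become supernodes by summing
M blocks). The quality of the returned partition always equals
`signed_modularity` recomputed from its labels — this self-consistency is
asserted in the tests, and on all-positive networks Q\* reduces exactly to
Newman modularity (checked against an independent implementation).

**Consensus clustering.** Louvain is stochastic. Each round runs it 100
times with distinct derived seeds; if all runs agree (pairwise ARI = 1)
the procedure stops, otherwise the co-assignment matrix A (fraction of
runs placing i and j together) is thresholded — entries below τ = 0.3
zeroed, diagonal removed — and becomes the next round's network. A is
non-negative, so re-clustering it is an all-positive special case of the
same optimizer. τ = 0.3 is a mid-range value from the consensus-clustering
literature; with 100 runs per round the procedure converged within 2–3
rounds in every experiment here, and a 50-round cap turns pathological
non-convergence into an explicit error carrying the last agreement matrix.
The final partition's Q\* is always evaluated on the *original* network.

On planted-partition benchmarks (three blocks of 40, within-edge
probability 0.9, between 0.1, no noise) consensus recovery is exact
(ARI = 1) in ≥95% of seeds, degrades monotonically with edge-weight noise,
and on ≤8-node instances the optimizer attains the exhaustive maximum over
all 4,140 partitions for separable instances and never exceeds it
otherwise.

## Subgroup statistics

* **Contrasts.** Scale-by-scale Mann-Whitney U tests for every subgroup
  pair (scores within subgroups are generally non-normal, which the
  Shapiro-Wilk screen documents). U is exact for small tie-free samples
  (n₁·n₂ ≤ 400), otherwise normal-approximated with tie correction. The
  Bonferroni family is all scales × pairs (18 for six scales, three
  groups).
* **Descriptives.** Median and unscaled MAD (median |x − median x|).
* **Enrichment.** For each diagnosis label, a 2 × K (label vs not, by
  subgroup) Pearson chi-square without continuity correction, df = K − 1;
  expected cells < 1 attach a warning instead of silently proceeding.
* **Homogeneity bootstrap.** The claim "data-driven subgroups are more
  homogeneous than diagnosis-based groups" is quantified by: per
  replicate, draw m children without replacement from every group of each
  grouping, compute the mean pairwise profile correlation within each
  subsample, average over groups, and take the difference d between the
  two groupings; report mean(d), SE = sd(d)/√reps and the one-sided
  p = max(#{d ≤ 0}, 1)/reps (so p is floored at 1/reps — 0.001 at the
  default 1,000 replicates). m defaults to ⌈0.65 × smallest group size⌉
  across both groupings (floored at 3); groups smaller than m are dropped
  with a warning, and children carrying no diagnosis are outside the
  diagnosis-based grouping entirely. Each grouping's subsampling stream is
  keyed to the grouping's content, not its argument position, which makes
  the statistic exactly antisymmetric under swapping the two groupings and
  exactly zero for self-comparison. "Mean pairwise child-child profile
  correlation" was chosen as the homogeneity kernel for consistency with
  the network construction (an alternative scale-by-scale correlation
  kernel would measure something different and is not the default).

## Connectome PLS

Connectomes are symmetric, non-negative, zero-diagonal FA-weighted region
matrices. Features are binary node degrees (count of edges above a weight
threshold, default 0) — degree is robust to FA-weight noise and keeps the
feature interpretable as "how connected is this region"; weighted strength
is available as an option.

The outcome is group membership coded as a one-hot indicator matrix,
column-centered; features are centered and unit-scaled (constant columns
dropped with a warning). PLS2 extracts components maximizing
covariance between features and indicators; per-component explained
outcome variance is the incremental R² of projecting the centered
indicator matrix onto the successive (orthogonal) score vectors, so the
entries are non-negative and cumulate to ≤100%. Components are retained
by a prefix rule: the longest leading run each explaining at least 5% —
with K groups the indicator matrix has rank K − 1, so later components are
noise by construction and are never interpreted.

**Evaluation.**

* Train/test split (60/40, stratified, degenerate splits redrawn):
  indicator RMSE on the test set against a null distribution from
  refitting on label-permuted training data; p = (#{null ≤ obs} + 1)/(B + 1).
  Under the null this p is calibrated: the measured type-I error at
  α = 0.05 lies within [0.02, 0.09] over 200 simulations.
* Stratified 10-fold cross-validated RMSE (mean ± SE over folds).
* **Bootstrap ratios.** Loadings are stabilized over bootstrap refits,
  each aligned to the full-sample reference loadings by an orthogonal
  Procrustes rotation (rotation/reflection only — no scaling — from the
  SVD of referenceᵀ·bootstrap) to resolve rotational indeterminacy;
  BSR = mean aligned loading / SD of the bootstrap distribution, with the
  SD floored at 1e-12 and |BSR| capped at 1e6 (capped entries are
  degenerate zero-variance cases and warn). The default resampling is an
  n-out-of-n bootstrap with replacement. A 60%-subsample-without-
  replacement variant (`frac=0.6, replace=False`) is provided, but it is
  not the default because measurement shows it mis-calibrates the ratios:
  subsamples share most of their members, so the across-draw SD
  understates the loading SE and ~11–12% of truly null regions exceed
  |BSR| > 2 where matched per-region t-statistics flag 5%; the
  with-replacement bootstrap measures ~7–8%. Regions are reported per
  component as the top quartile of |BSR| (boundary ties included), with a
  reliability flag at |BSR| > 2.

On synthetic connectome sets with +8-edge degree effects implanted on four
regions per group (2 × 30 participants, 34 regions, base density 0.3),
the pipeline flags ≥90% of effect regions and ≤10% of null regions and
detects the effect by permutation test in ≥95% of seeds.

## Synthetic generators

The generators define the test bed; they are deliberately simple so that
every downstream claim has a computable ground truth.

* **Cohorts.** k latent groups (default three: cognitive-control,
  learning, conduct), each child's six scores drawn as group median +
  independent normal noise with sd = 1.4826 × MAD — the normal
  distribution matching the published per-cluster medians and MADs of a
  referred cohort of 442 children. Ages are uniform over 62–215 months
  (no planted age effect; the residualization stage must not invent one),
  sex is Bernoulli(295/442 male), a negative-impression flag is
  Bernoulli(80/442), and diagnosis labels follow the published
  cluster-by-diagnosis enrichment (ADHD concentrated in the
  cognitive-control group, learning deficits in the learning group). A
  T-like age-standardized score per scale is derived from the
  standardized raw score via the published whole-sample T means/SDs,
  clipped to [20, 100].
* **Planted-partition networks.** Near-equal communities; within-community
  edges present with p_within, between with p_between, present edges have
  weight 1 + N(0, noise_sd²).
* **Connectomes.** Edges Bernoulli(base_density) with FA-like uniform
  weights; for a participant's group, edges incident to that group's
  effect nodes get presence probability raised by effect_size/(n − 1), so
  the expected *binary* degree of each effect node rises by ≈ effect_size
  edges (implanting through presence rather than weight keeps the effect
  visible after binarization).

All generators are deterministic given one integer seed.

**What the synthetic tests show — and what they do not.** Independent
normal noise at the published within-cluster MADs is a *hard* condition
for Q-mode correlation clustering: the within-group profile coherence it
produces (mean within-group child-child r ≈ 0.21, between ≈ −0.10 at the
default profiles) is weaker than in an empirical network whose clusters
were carved from the same data by quality maximization, because published
within-cluster spreads describe already-optimized partitions and real
scale noise is neither independent nor normal. Consequently consensus
clustering on these cohorts reliably finds the three generating
communities, but with a median quality index around 0.43 — clearly
positive yet below values reported for empirical full-sample networks
(≈0.55), and the adjusted Rand index against the generating groups is
moderate rather than perfect. Passing these tests therefore establishes
that the pipeline recovers the number and identity of planted subtypes
under realistic noise; it does not establish the quality level to expect
on a specific real cohort, which depends on the true noise correlation
structure.

Problem sizes used by the test suite and the acceptance script (ten
450-child cohorts; 20-seed planted-partition and PLS recovery batteries;
200-replicate null calibrations; 200–500 bootstrap draws) were chosen as
the smallest batteries whose pass/fail criteria are stable across seeds.

## Known limitations

* The six-point profiles make single edges noisy; cohorts below ~50
  children per expected subgroup yield unstable partitions.
* The age model is linear; strongly nonlinear age trends would leak into
  the residuals.
* The homogeneity statistic compares groupings on the same scales used to
  form the data-driven grouping; validating subtypes on held-out
  instruments requires supplying those instruments' scores as a second
  residual table.
* PLS evaluation treats participants as exchangeable; family or site
  structure is not modeled.
* The consensus procedure assumes the agreement matrix is informative; at
  τ near 1 or with very few runs per round it can oscillate (the round cap
  converts this into an explicit error).
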