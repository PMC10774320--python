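# Methods

This note records the statistical model behind `mechnet`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer should know about. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Activity model

**Single-sample signatures.** Expression is standardized per gene across the
cohort (mean 0, sample sd 1, `ddof=1`). The signature of sample *j* is its
gene z-score vector; ranking is by descending score with ties broken by
ascending gene identifier, so orderings are deterministic. Constant genes are
mapped to all-zero rows with a warning: they carry no rank information, and
zeroing avoids NaN propagation.

**Enrichment statistic.** For a query set of k genes in an N-gene signature,
the enrichment score (ES) is the signed extremum of the weighted
Kolmogorov–Smirnov running sum: in-set steps are proportional to
`|score|^p · w` (default exponent `p = 1`; `p = 0` gives a rank-only
statistic invariant under monotone score transforms), out-of-set steps are
`-1/(N-k)`. An exact tie between the positive and negative extremum resolves
to the positive one, with a `1e-12` tolerance so float summation-order noise
cannot flip the branch.

**Null, p-value, NES.** The null permutes gene labels (equivalently, places
the k-set uniformly at random), 1000 draws by default. The p-value is the
one-sided tail with add-one smoothing, `(1 + #{null ≥ ES}) / (1 + n_perm)`
for positive ES, so `p ≥ 1/(n_perm+1)` always. NES divides ES by the mean
|ES| of the same-sign null scores (positive and negative nulls normalized
separately, preserving sign symmetry). A query set overlapping the signature
by fewer than `min_overlap` genes (default 5) yields a skipped result, not an
estimate.

**Regulon (TR-program) scoring.** A TR program is a TF/co-factor with
targets, each carrying a mode of regulation in [-1, 1] and a likelihood in
(0, 1]. Scoring negates the signature scores of negative-mode targets,
re-ranks, and runs the same weighted-KS statistic with per-target step
weights `|mode| · likelihood`; zero-weight targets are dropped. This is a
deliberately simple, fully specified scheme (testable against a sign-flip
oracle) rather than a three-tailed regulon-enrichment algorithm with
pleiotropy correction; the NES retains the same interpretation (positive =
program active). One consequence worth knowing: flipping every mode negates
the ES *exactly* only when the non-target score distribution is symmetric
about zero (z-scored signatures are approximately so); in general the
re-ranking makes the antisymmetry approximate. The NES ratio additionally
carries finite-permutation noise, so mode-flip antisymmetry of NES is
asymptotic in `n_perm`.

**Shared nulls.** Within one sample, sets of equal size share one
permutation-position draw per mechanism kind (the member weights still apply
per set): the marginal null is identical and the cost drops by the number of
equally sized sets. Pathway and TR nulls use independent streams so that
shared null-normalization noise cannot correlate TR estimates with pathway
estimates — those correlations are exactly what the network stage measures.
Per-sample streams are derived from `(seed, crc32(sample id))`, which makes
activity values invariant (to float summation order, asserted at 1e-9) under
sample reordering.

**Contrast signatures.** Phenotype contrasts use the two-tailed Welch t
statistic per gene (positive = up in the later phenotype), with p-values kept
in the signature metadata. Zero-variance genes get t = 0.

## Network model

Each pathway activity vector is regressed on each TR activity vector by
ordinary least squares (`pathway = α + β·TR`); the slope's two-sided t-test
p-value is floored at 1e-300. Benjamini–Hochberg correction runs within each
pathway (across its TRs), never globally; pairs with FDR below 0.05 (default)
become edges signed by the slope. At least 3 shared, identically ordered
samples are required; constant activity vectors are an error.

**Bootstrap weights.** The cohort's samples are resampled with replacement
`k = 100` times (default); each edge's weight is the percentage of resampled
networks containing it *with the same sign*. Weights qualify the base
network's edges; resampled-only edges are never added. Two resampling modes:

* `resample_activities` (default): resample columns of the precomputed
  activity matrices. Fast, and exact if activities were per-sample quantities.
* `full_recompute`: resample expression columns, re-z-score, re-enrich,
  rebuild. Faithful to the cohort-level z-scoring (a resample changes each
  gene's mean/sd), but orders of magnitude slower.

The approximation error of the default mode is the dependence of the z-score
normalization on the resample; on small simulated cohorts the two modes
agree on edge weights to within the bootstrap's own Monte-Carlo noise
(asserted in the tests at a 30-point mean tolerance with k = 10). Degenerate
resamples (fewer than 3 distinct samples, or any constant vector) are
redrawn and logged.

## Mining ("up-down-up")

Candidates are the network neighbours of the queried pathway — mining is a
sub-network query, not a transcriptome-wide screen. Each candidate TR program
(and the pathway's own gene set) is enrichment-scored in both contrast
signatures; passing requires NES < 0 with p below threshold (default 0.001)
in the untreated→sensitive contrast and NES > 0 with p below threshold in
the sensitive→resistant contrast. `n_perm` must satisfy
`1/(n_perm+1) < p_threshold`, otherwise the threshold is unreachable by
construction (enforced; 1999 permutations suffice for p < 0.001). The
pathway itself must pass for the result to be flagged coherent; if it does
not, passing TRs are still reported with `pathway_passes = False` rather
than raising. "Active in the untreated state" is encoded by the two
contrasts, not tested separately.

## Prioritization

**VIF.** Each TR activity vector is regressed on all the others (OLS with
intercept when samples > TRs; a small-ridge fallback, flagged in the report,
otherwise); VIF = 1/(1−R²), with VIF > 10 read as multi-collinear. Collinear
TRs are kept — the latent-variable construction exists precisely to handle
them — the report is diagnostic.

**Latent variables.** Per component: each TR's weight is the univariate OLS
slope of the (deflated) pathway vector on that (deflated) TR vector; the
weight vector is normalized to unit Euclidean norm so the component scores
are invariant to rescaling individual TRs (raw slopes are scale-dependent;
the normalization is this package's choice where the construction leaves it
open). Scores are the weight-combination of the deflated TR block; loadings
are the multivariable OLS coefficients of the score on the TR block
("contribution adjusted for all other TRs"). Both the TR block and the
pathway vector are then replaced by their residuals on the score (with
intercept), which makes successive score vectors *exactly* uncorrelated
(Pearson r = 0 up to float error; asserted at 1e-8). Default 2 components —
the correlation circle needs exactly two axes; an optional
explained-variance stopping rule halts when a component explains less than
1% of the original pathway variance. Degenerate deflated blocks stop the fit
early with a reason.

**Circle of correlation.** Each TR and the pathway get coordinates
`(r(vector, scores₁), r(vector, scores₂))`. Because the score vectors are
uncorrelated, every point lies within the unit circle (asserted at 1e-9).
The inclination angle uses the full-circle `atan2` convention in [0, 360) —
an arccos of the x-coordinate alone cannot distinguish quadrants — and
angular closeness to the pathway arrow is the wrapped absolute difference
`min(|Δ|, 360−|Δ|) ∈ [0, 180]`, a true metric. Whether closeness should be
signed cannot be settled from first principles; the absolute convention is
used throughout.

**Grouping and effect scores.** TRs are clustered on their 1-D closeness
values with complete-linkage agglomerative clustering; the cut is user-set
or chosen by maximum silhouette over 2..min(10, #TRs−1). Singletons are
legitimate groups. Each group is ranked (1 = best, ties get average ranks)
on (i) mean closeness (smaller better), (ii) mean |r| of its members with
the two evaluated latent axes (larger better; absolute value because both
poles of a latent axis carry effect), (iii) mean bootstrap edge weight
(larger better). The effect score is the geometric mean of the three ranks;
`final_rank` orders groups by ascending effect score. Every group member
must have a (weighted) network edge to the pathway — a violation is a
contract error, not a silent drop.

## Cohort utilities

* **Overlap index**: `|A∩B| / (|A|+|B|)` by default — note this caps at 0.5
  for identical sets — with the classical union-denominator Jaccard
  available; the report records the convention. The sum convention is the
  package default because it is the written form of the statistic being
  reproduced, and both conventions agree at the printed precision on the two
  reference checks (0.007 and 0.01).
* **Cook's screen**: Cook's distance from the simple linear fit, flagged at
  `D > 4/n` (a standard rule; configurable absolute cutoff). A (near-)exact
  fit makes Cook's D a 0/0 form, so fits with relative residual variance
  below 1e-12 flag nothing.
* **Stratification**: k-means (k = 2, seeded) supplies the labels;
  complete-linkage hierarchical clustering runs alongside and the fraction
  of identically assigned samples is reported. The `high_high` cluster is
  the one with the larger centroid coordinate sum. Threshold transfer uses
  the per-axis minima of the training high/high cluster, compared
  inclusively — the operational definition chosen here for "applying the
  same thresholds" to a sibling cohort.
* **Survival**: log-rank test plus Cox proportional hazards (optionally
  covariate-adjusted) via lifelines; a group with no observed events is a
  warning, not an error. For binary-response cohorts the contract predictor
  is the product of the two activities, evaluated by AUROC.

## Synthetic data

`make_cohort` draws latent per-sample TR activities (standard normal),
whitens them across TRs (exact in-sample decorrelation, requires
samples > TRs) so that the planted TR→pathway edges are the *complete*
ground truth — without whitening, chance latent correlations (|r| ≈ 0.3 at
n = 80) produce real-but-unplanted associations that a sensitive detector
correctly finds, making "precision against planted edges" ill-defined.
Target genes follow `mode · effect · activity + noise`; pathway genes follow
the planted linear combination of parent activities plus noise; all other
genes are standard-normal noise. Gene blocks are disjoint. Defaults — 80
samples, 1200 genes, 30 TRs × 25 targets, 10 pathways × 25 genes, effect
1.0, noise sd 0.5 — are the package's reference study conditions: desk-scale
sizes with per-gene SNR 2, at which edge recovery is expected to be
essentially exact, chosen once and used unchanged by the recovery tests.

`make_phenotype_series` holds all structure fixed and sets the listed TRs'
latent activity to +e / −e / +e across the three phenotype groups (default
e = 2, four samples per group, matching a small cell-line design).
`make_collinear_block` mixes one or few shared factors into every TR
(mixture magnitudes in [0.8, 1.2], noise sd 0.1), which guarantees VIF > 10
at the default noise. `make_survival` draws exponential event times with
group-specific hazards; censoring is independent exponential with per-group
rate proportional to the hazard, calibrated so the expected censored
fraction equals `censor_rate` exactly in each group. A side effect of that
calibration is worth knowing: at 10% censoring it measurably biases
small-sample Cox estimates upward, so the CI-coverage tests run uncensored.

What the generator does **not** emulate: count noise (negative binomial),
batch effects, copy-number confounding, overlapping regulons, TR–TR
regulation, non-linear TR→target links. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its own
assumptions (linear links, Gaussian noise, disjoint programs), not
performance on real cohorts.

`make_prioritization_scenario` composes the pieces into the prioritization
benchmark: one dominant TR generating the pathway signal among ten collinear
decoys that are independent of the pathway. Because effect scoring requires
every candidate to be a network neighbour, the scenario's base network keeps
all candidate edges (permissive FDR cut) while bootstrap weights are
computed at the working FDR of 0.05 — decoy edges exist but carry near-zero
stability, exactly the situation the effect score is meant to resolve.

## Numerical choices, in one place

* Ranking ties: stable sort by (score desc, gene id asc).
* ES extremum ties: positive branch, 1e-12 tolerance.
* p-value floors: `1/(n_perm+1)` (permutation), 1e-300 (OLS slope).
* Zero-variance: genes → zero rows (warn); activity vectors → errors;
  deflated PLS blocks → early stop with reason; exact linear fits → Cook's
  distances all zero, bootstrap p floor.
* Seeds: every stochastic routine takes an explicit seed; per-entity streams
  derive from `(seed, crc32(entity id))` so results are invariant to entity
  order. Bootstrap weights are bit-reproducible given (seed, k, mode).
* Serialization: TSV/GMT, UTF-8, tab-separated, 6 significant digits,
  sorted row ids.

## Known limitations

* The regulon statistic ignores target-overlap pleiotropy between TRs; two
  TRs sharing many targets will show correlated activities by construction
  (the VIF/latent-variable stage is the mitigation, not the scorer).
* `resample_activities` bootstrap underestimates the variability contributed
  by cohort-level re-standardization; use `full_recompute` when that matters
  and time allows.
* Effect-score criterion (ii) uses the two circle axes; with more than two
  fitted components the additional axes do not enter the ranking.
* The sum-denominator overlap index is not the classical Jaccard; reports
  carry the convention to prevent cross-study confusion.
* Survival evaluation assumes proportional hazards and uses Wald CIs, whose
  finite-sample coverage at ~100 events is a little below nominal.
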