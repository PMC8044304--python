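# Methods

`csfprofile` implements a data-driven profiling pipeline for the three CSF
core Alzheimer biomarkers — the Abeta42/Abeta40 concentration ratio, p-tau
(phosphorylated at Thr181), and total tau, all in pg/mL except the
dimensionless ratio.  This note records the models, the numerical choices,
and the limits of what the synthetic validation shows.

## The synthetic cohort generator

Real subject-level cohorts of this kind are shared only on request, so the
package ships a generator that encodes the statistical structure the analysis
stages assume, and every study-scale test runs against it.

Each subject is drawn from a six-component trivariate Gaussian mixture over
(ratio, p-tau, t-tau) in natural units, with weights
π = (0.30, 0.10, 0.20, 0.15, 0.15, 0.10):

| component | profile | ratio | p-tau (pg/mL) | t-tau (pg/mL) |
|---|---|---|---|---|
| 1 | control-like | 0.095 (SD 0.012) | 30 (SD 6.5) | 220 (SD 50) |
| 2 | heterogeneous | 0.075 (SD 0.020) | 65 (SD 30) | 900 (SD 600) |
| 3–6 | AD-like | 0.045 (SD 0.008) | 55 / 80 / 110 / 150 | 350 / 550 / 800 / 1200 |

Within components, p-tau and t-tau are correlated (ρ = 0.2); the ratio axis
is independent.  The AD-like tau SDs (6.5–10 for p-tau, 50–110 for t-tau)
place adjacent components roughly three within-component SDs apart in each
tau dimension.  This spacing is the deliberate design point of the
generator: it makes the six-component structure identifiable by BIC at
n = 616, which is the regime the whole pipeline is meant to operate in.  A
mixture whose components overlap beyond recoverability would not exercise
the model-selection or labeling stages meaningfully.

Negative draws are rejected and redrawn (up to 100 rounds, then clamped at
1e-6): rejection distorts the component covariance less than hard truncation.
One consequence worth knowing: the heterogeneous component's realized t-tau
mean sits ~50–60 pg/mL above its nominal 900 because its SD of 600 puts real
mass below zero.  Parameter-recovery tests therefore compare fitted means to
the *realized* per-component means (via the retained `_component` truth
column), not the nominal ones.

Clinical annotation is layered on top: each component carries a categorical
distribution over a 20-term diagnosis vocabulary (AD, OND, FTD, PD, DLB,
CJD, NPH, ...).  By construction ≥ 90% of AD subjects arise in AD-like
components and ≥ 70% of OND subjects in the control component — the regime
in which prevalence-based cluster labeling is well posed.  Ages are
truncated normals per diagnosis (AD ~ N(72, 8), OND ~ N(58, 12), others
N(68, 10), truncated to 40–90 years) — deliberately imbalanced so the
matching stage has real work to do.  Sex is Bernoulli per diagnosis
(AD 55% F, OND 45% F, PD 35% F, otherwise 50%).  Abeta40 is drawn
independently of the mixture (truncated N(11000, 2500²), 4000–20000 pg/mL)
and Abeta42 = ratio × Abeta40: amyloidosis expresses through the ratio, not
through Abeta40.

Paired two-center remeasurement multiplies each true value by (1 + ε) with
ε ~ N(0, cv²) independently per center.  Default CVs: ratio 7%, p-tau 4%,
t-tau 9%, Abeta42 12%, Abeta40 9%.  Note that with the two-point CV
convention below, the *expected mean per-pair CV* is cv·√(2/π) ≈ 0.8·cv
(half-normal mean), not cv itself.

What the generator does **not** emulate: longitudinal trajectories, missing
data, assay drift beyond proportional noise, skewed or heavy-tailed
within-cluster biomarker distributions (real tau distributions are
right-skewed), and diagnosis-dependent biomarker distributions *within* a
component.  Tests passing on this generator show the pipeline's statistics
are implemented correctly and behave as designed at study scale — they do
not certify performance on real cohorts.

## Inter-center concordance

**Passing-Bablok regression** (original 1983 procedure): the slope is the
shifted median of all pairwise slopes S_ij = (y_j − y_i)/(x_j − x_i), i < j,
excluding S_ij = −1 and vertical pairs; with N kept slopes and K of them
below −1, the estimate is the element at rank ⌈(N+1)/2⌉ + K (odd N) or the
mean of ranks N/2 + K and N/2 + 1 + K (even N).  Identical pairs contribute
nothing.  The intercept is median(y − b·x).  CIs are paired percentile
bootstrap (2000 resamples by default; replicates whose pairwise slopes are
all excluded are skipped).  The bootstrap is fully vectorized
(replicate × pair slope matrices, chunked to bound memory).  Exact scale and
shift equivariance holds whenever no pairwise slope falls at or below −1
(always the case for positively correlated method-comparison data); with
negative slopes present the exclusion set itself depends on the scale, and
exactness is lost by construction of the estimator.

**Inter-assay CV** per sample: for a duplicate pair (a, b),
CV = SD/mean with the two-point sample SD |a − b|/√2.

**PCA**: eigendecomposition of the sample covariance (n − 1) of the pooled
z-scored matrix; loadings are sign-fixed (largest-magnitude element
positive) for deterministic output.  Per-cohort 95% ellipses in the PC1–PC2
plane use the bivariate-normal Mahalanobis radius √χ²₀.₉₅(2) ≈ 2.448 on that
cohort's score covariance.

**Mergeability rule**: an analyte is poolable when the slope CI contains 1
and either the intercept CI contains 0 or |intercept| < 5% of the median
measured value — small offsets relative to nominal concentrations do not
preclude pooling (t-tau is the canonical case).  The 5% fraction is a
configurable judgment call.

## Clustering

Biomarkers are z-scored (pooled two-center moments, n − 1 SD) before
fitting; profiles are reported back in natural units.  Pooling is deliberate:
the centers are merged before clustering, so one set of moments describes
the clustered data.

The mixture is fitted by EM with full covariances.  Initialization is
emEM-style: each of n_init = 10 chains burns in 5 k-means++-seeded
candidates (Lloyd-refined to convergence) for 20 EM iterations and continues
the best by likelihood.  Short-run likelihood predicts the final basin far
better than k-means inertia; conversely, concentrating all chains into the
single best k-means solution was tried and rejected — basin diversity across
chains is what rescues hard datasets.  Convergence: relative log-likelihood
change < 1e-6, max 500 iterations; 1e-6 is added to covariance diagonals
each M-step.  Hard labels are responsibility argmaxes.

K is chosen by minimizing BIC = −2 logL + p·ln n with
p = (K − 1) + 3K + 6K for d = 3; ties within 1e-9 break toward smaller K.
On the default generator at n = 616, K* = 6 in 19 of 20 fixed seeds (the one
exception genuinely prefers K = 4 at any initialization effort — sampling
noise, not an optimizer failure).

Cluster annotation: per-cluster medians with the 95% data range
(2.5th/97.5th percentiles, linear interpolation between order statistics);
a prevalence matrix over diagnoses with ≥ 5 subjects (rows sum to 100%);
UPGMA/Euclidean ordering of heatmap rows and columns.  *Control* is the
cluster with the largest share of all OND subjects (ties break toward higher
median ratio); *AD-like* clusters hold ≥ 10% of all AD subjects and more AD
than OND members; the control cluster qualifying as AD-like is an error
(pathological data).  The misdiagnosis tolerance is the smallest number of
OND→AD relabelings that changes this labeling; since the labeling depends
only on per-cluster AD/OND counts, the search reduces to exact counting over
single-cluster relabeling strategies (concentrating relabelings in one
cluster is weakly optimal), verified against exhaustive enumeration in tests.

Fisher's exact test (two-sided, conditional hypergeometric) is used to
compare MCI-phase vs dementia-phase AD prevalences across AD clusters; the
implementation delegates to scipy and is test-verified against explicit
enumeration.

## Cut-offs

Per biomarker and comparison, candidate thresholds are midpoints between
adjacent distinct values plus ±∞ sentinels; the cut-off maximizes Youden's
J = sensitivity + specificity − 1.  Directions are fixed a priori by
biology: ratio low = AD-positive; p-tau and t-tau high = AD-positive.  Ties
break by highest sensitivity, then toward the more specificity-conservative
threshold.  The ranking is integer-exact (J·n_pos·n_neg is an integer), so
tie-breaks are never decided by floating-point rounding — this matters when
cross-checking against any independent implementation.

CIs are stratified percentile bootstrap (resampling within positives and
negatives separately, 2000 replicates), enveloped around the point estimate
so the reported triple is always ordered.  The three standard comparison
families: clinical (AD vs OND), control cluster vs AD-like union, and each
intermediate cluster vs the AD-like union; for intermediate comparisons both
orientations are reported, because a heterogeneous (e.g. CJD-heavy) cluster
can exceed the AD clusters in t-tau, making the positive direction genuinely
ambiguous.

## Age/sex matching

Age histogram matching uses fixed [5k, 5(k+1)) year bins anchored at zero;
within each bin the larger group is randomly down-sampled to the smaller
count and one-sided bins are dropped entirely.  Sex is then rebalanced one
subject at a time — removing a random member of the over-represented sex
from the group where it is over-represented — until a logistic regression of
group membership on age and sex (self-contained IRLS MLE, Wald tests)
shows p > 0.25 for both covariates.  One-at-a-time exclusion is the smallest
perturbation able to cross the threshold and keeps the retained set
reproducible from the seed.  The iteration guard defaults to half the
subjects: strong imbalances (90% vs 50% male at n = 200 per group) genuinely
require ~40% of subjects excluded before the Wald test goes quiet, so a
tighter guard would reject feasible problems.  Complete separation in the
logistic fit (|linear predictor| > 30) is flagged, not silently returned.

Cut-offs are then recomputed on the matched subset and compared with the
unmatched ones; "unchanged" is operationalized as the matched point estimate
falling inside the unmatched 95% CI.

## Problem sizes and determinism

Study-scale checks run at n = 616 subjects (the merged-cohort scale this
kind of analysis targets), 40 paired samples for concordance, 2000 bootstrap
replicates, and 20 fixed generation seeds for the consistency properties;
property suites use 100–500 randomized instances with fixed seeds.  All
randomness flows through `numpy.random.default_rng` seeds, so every reported
number is bit-reproducible.

## Known limitations

* Gaussian components cannot represent the right skew of real tau
  distributions; on real data the heterogeneous cluster in particular may
  absorb or shed an extra component.
* The mergeability rule's 5% intercept allowance and the 10% AD-share
  labeling threshold are conventions, not estimates; both are exposed as
  parameters.
* The misdiagnosis tolerance assumes the labeling rule itself is fixed;
  it measures robustness of the labeling, not of the cut-offs.
* Percentile-bootstrap CIs are first-order accurate only; BCa was not
  implemented.
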