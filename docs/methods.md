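# Methods

This note documents the statistical procedure implemented by `delirclust`,
the choices that were genuinely open, and what the synthetic cohort does and
does not establish.

## The two-stage clustering model

The input is a complete panel of ordinal severity scores: n participants ×
13 items × 5 days, each score in {0,…,3}. Flattened to the wide matrix
X ∈ ℝ^(n×65) (columns `item@day`, day-major order), the analysis makes no
longitudinal-model assumptions: time enters only through the column
identity of each cell.

**Stage 1 (feature grouping).** The 65 columns of X are treated as points
in ℝ^n and clustered by K-means. Columns that rise and fall together across
participants — e.g., the sleep item on all five days — land in one group.
Each group is collapsed to its per-participant mean, giving X̃ ∈ ℝ^(n×G).
This is a hypothesis-free alternative to fixed composite scores: the
grouping is estimated, not imposed. Columns are clustered on the raw 0–3
scale, not z-scored, because all 65 cells share one ordinal scale and
standardization would inflate the noise of near-constant cells; a
`standardize=True` option exists for sensitivity analysis.

**Stage 2 (participant clustering).** Rows of X̃ are clustered by the same
engine. Clustering on composites rather than the raw 65 columns absorbs the
strong within-group correlation of the original cells and makes the
resulting clusters directly interpretable in terms of the grouped features.

Both stages are descriptive: the fitted partition characterizes the cohort;
it is not a predictive model of individual trajectories.

## The K-means engine

Lloyd's algorithm with squared-Euclidean distances; initial centroids are K
distinct data points sampled uniformly; assignment ties break to the lowest
cluster index; an empty cluster is reseeded at the point farthest from its
assigned centroid (the point is force-assigned, so all K indices always
occur). Iteration stops when assignments stabilize, every centroid moves
less than `tol` = 1e-6, or `max_iter` = 300 is reached. The returned
solution is self-consistent: centroids are the means of the returned
assignment and the WCSS is the objective of that partition. The
within-cluster sum of squares is non-increasing across iterations (asserted
in tests).

Because single runs find local optima, model-order selection runs every
candidate K (default 1..10) `restarts` times (reference protocol: 1000;
tests and examples use 40–200, chosen as the point where the selected K and
recovered partitions stop changing on the reference cohort) and takes the
global argmin of the criterion over the full (K, restart) table. Per-run
seeds are the entropy tuple `(master_seed, K, restart)` fed to NumPy's
`default_rng`, so any individual run is replayable in isolation and the
whole sweep is reproducible from one integer. Criterion ties break to the
smaller K, then the earlier restart.

## The model-order criterion

Two AIC-style criteria are implemented behind one interface:

- `profile`: n·d·ln(max(WCSS/(n·d), ε)) + 2·K·d, the AIC of a spherical
  Gaussian mixture with shared variance profiled out (ε = 1e-12 floors
  perfect fits);
- `distortion` (default): WCSS + 2·K·d, the penalized-distortion AIC in
  which the distortion plays the role of the deviance and each centroid
  contributes d parameters.

The choice matters and the two regimes of this pipeline expose it. In stage
1 (65 points in ℝ^286) both forms select the planted G = 4. In stage 2 (286
points in ℝ^4) the profile form reliably overfits to the top of the K range:
the scores are discrete, every split of a large cluster shrinks WCSS by a
non-trivial *factor*, and the log-likelihood term rewards multiplicative
shrinkage with only 2·d = 8 points of penalty per extra cluster. The same
failure shows on a textbook case — two tight, well-separated Gaussian blobs,
where the profile form prefers K = 6 over the correct K = 2. The distortion
form compares *absolute* WCSS reduction against the penalty and selects the
planted K = 7 (and K = 2 on the blobs) across seeds. It is therefore the
default for both stages; the profile form remains available
(`criterion="profile"`) for users who want the likelihood-based variant.

## Cluster characterization

- **Severity ordering:** clusters are ranked by the within-cluster mean of
  each member's maximum daily total score (range 0–39); rank 1 = most
  severe; ties break to the smaller raw index.
- **Diagnosis labeling:** a cluster is labeled *delirium* iff its diagnosed
  members are at least as many as its undiagnosed members (ties go to
  delirium — the clinically conservative side); participants with missing
  diagnoses are excluded from the counts.
- **Post-hoc battery:** for each of the m = K × G (cluster, grouped
  feature) pairs, a one-sample t-test of the cluster's composite values
  against the cohort-wide mean of that composite. The family is all m tests
  jointly — the stricter reading — controlled by Bonferroni at family-wise
  α = 0.05 (reject iff raw p ≤ α/m). The baseline includes the tested
  cluster's own members, which biases the tests conservative under the
  null; this is documented behavior, not corrected, because the baseline is
  defined as the overall cohort average. Zero-variance samples are handled
  explicitly: (t, p) = (0, 1) when the mean equals the baseline, (±∞, 0)
  with a warning otherwise.
- **Grades:** significant cells are graded +/++/+++ (or −/−−/−−−) by
  binning the Bonferroni-corrected p at 0.05 / 0.01 / 0.001. The grade
  bins are a package convention for readable tables, not an inferential
  claim beyond the α-level rejection.
- **Interpretation:** the direction pattern of each cluster over the four
  roles (motor, cognitive, acute, sleep) maps to one of seven named
  clinical-style archetypes (e.g., only sleep elevated → "insomnia"; all
  depressed → "fit"); anything else is "unclassified pattern". Role
  assignment mirrors the visual-inspection step a human performs: the group
  dominated by the sleep item takes the sleep role, the day-1-dominated
  group the acute role, the group richest in cognitive/higher-order items
  the cognitive role, the remainder motor.
- **Covariate screen:** one-way fixed-effects ANOVA per covariate across
  clusters, complete-case per covariate; clusters with fewer than two
  non-missing values are excluded with a warning.

## PCA views

Covariance PCA on centered, unscaled data (consistent with clustering raw
scores): scores are projections onto the top-2 right singular vectors, with
the deterministic sign convention that each component's largest-magnitude
loading is positive. The numeric scatter TSV is the tested artifact; the
PNG is cosmetic.

## The synthetic cohort

The generator emulates the *structure* of a postoperative severity panel,
not the distribution of any particular dataset:

- 286 participants from 7 archetypes of sizes 6, 8, 13, 28, 26, 80, 125;
  per-archetype delirium-label probabilities 6/6, 8/8, 13/13, 27/28, 20/26,
  12/80, 5/125 (Bernoulli draws, so realized counts vary by seed).
- A planted partition of the 65 cells into 4 groups: sleep item days 1–5
  (5 cells); all other items on day 1 ("acute", 12 cells);
  cognitive/higher-order plus perception/content items on days 2–5
  (36 cells); the remaining motor/affect cells on days 2–5 (12 cells).
  This partition is configuration (editable JSON/YAML), and is an explicit
  approximation of the qualitative grouped-feature description it mimics.
- Archetype group means: 2.0 where a group is elevated, 0.5 background,
  0.2 suppressed — conventions tuned so that recovery at the default noise
  is achievable but not trivial.
- Scores: round(clip(mean + N(0, noise_sd), 0, 3)) with noise_sd = 0.4 by
  default (NumPy round-half-even). An optional AR(1) latent (`ar1_rho`)
  correlates an item's noise across days; the default is independent noise,
  since the true day-to-day autocorrelation of such panels is unknown.

What passing recovery tests shows: the pipeline identifies planted block
structure of realistic size and noise, with the documented selection
criterion, at ARI = 1.0 on the reference seed and ≥ 0.9 across seeds at low
noise. What it does not show: performance on real cohorts, whose noise is
not i.i.d. discretized-Gaussian, whose cluster separations are weaker and
unevenly spread, and whose covariates correlate with cluster membership.
Two concrete artifacts of the simulation worth knowing:

- The post-hoc battery on the synthetic cohort has enormous power, so
  composites only slightly off the cohort baseline reach significance and
  several clusters fall to "unclassified pattern" rather than their
  idealized named archetype; the named patterns (insomnia, fit, prolonged)
  still emerge where the planted contrasts dominate.
- The simulated covariates (age, MMSE) intentionally carry no cluster
  signal; their ANOVA p-values are approximately uniform, which is the
  calibration check, not a clinical claim.

## Numerical and degenerate-input conventions

- Missing score cells are a hard error; the pipeline analyzes complete
  participants only (no imputation).
- WCSS floor ε = 1e-12 in the profile AIC; WCSS = 0 partitions are valid.
- All-identical points select K = 1; K > n is rejected.
- Bonferroni contract is exact: significant iff raw p ≤ α/m, both
  directions asserted in tests.
- The null-FWER simulation reports the Monte-Carlo SE alongside the rate;
  the calibration check allows 2 SEs above α.

## Problem sizes used by the test suite

The reference protocol (1000 restarts per K) is the library default; the
test suite and examples run the same sweeps at 40–200 restarts, sizes at
which the selected K and the recovered partitions on the reference cohort
are stable across master seeds (checked over seeds 1–8 at 100 and 200
restarts). The FWER calibration uses 500 replicates; the noise-robustness
property uses 5 seeds per noise level at 40 restarts.
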