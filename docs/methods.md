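# Methods

## The individualized differential SCN statistic

The reference network rSCN is the sample Pearson correlation matrix of
regional cortical thickness over the n control subjects. For patient *k* the
perturbed network pSCN(k) is recomputed from scratch over the n + 1 stacked
rows (no incremental update — exactness is cheap at these sizes). The
edge-wise statistic is

    Z_e = (pSCN_e − rSCN_e) · (n − 1) / (1 − rSCN_e²),

with two-sided p-values from the standard normal reference and Bonferroni
correction over all M(M−1)/2 distinct edges. Edges with |rSCN| = 1
(numerically degenerate, e.g. duplicated regions) are flagged, excluded from
the test count, and carry z = 0, p = 1. p-values are floored at the smallest
positive double so the (0, 1] invariant holds. The significance comparison
is strict (`p < α/n_tests`).

### Actual sampling behaviour of Z (important)

Adding one subject to n controls changes a sample correlation by
approximately IF/(n + 1), where IF = x̃ỹ − (r/2)(x̃² + ỹ²) is the influence
function evaluated at the new subject's standardized values. Z therefore has
mean ≈ the patient's generative correlation deviation divided by (1 − r²),
and patient-to-patient standard deviation ≈ 1 — but its *shape* is that of a
product of Gaussians, not a Gaussian: excess kurtosis ≈ 5, exponential
tails, Kolmogorov–Smirnov distance ≈ 0.10 from N(0, 1). Consequences,
measured by simulation in the test suite and the acceptance script:

- Normal p-values are anti-conservative in the far tail. Under a pure null
  (patients drawn from the control distribution, n = 89, M = 148), the mean
  number of Bonferroni-significant edges per patient is of order 40–80, not
  α. Per-patient "significant" edge sets should be read as the patient's
  most extreme deviations, not as familywise-calibrated discoveries.
- A generative correlation shift of δ at one edge moves that edge's expected
  Z by about δ/(1 − r²) with unit-scale noise, so single edges reach the
  Bonferroni threshold (|Z| ≈ 4.5) only for extreme individual deviations;
  subtype structure lives in the continuous Z features, not in the
  significance flags.

These are properties of the statistic itself; the implementation reproduces
the method as published (normal reference, no Fisher transform).

## Jackknife heterogeneity

Each subject's individualized network is the jackknife pseudovalue
n·C − (n−1)·C₋ᵢ of the group correlation matrix (diagonal forced to 1), and
the subject's deviation is the Euclidean distance between pseudovalue and
group network over the strict upper triangle. Groups are compared with a
pooled-variance two-sided t-test; Cohen's d uses the pooled SD and carries
the sign of mean(A) − mean(B). Distances are invariant to subject order and
to adding a constant to all thickness values.

Two structural facts about this statistic, established by simulation:

- The pseudovalue distance is an almost deterministic increasing function of
  the subject's leverage ‖x̃ᵢ‖² (empirical correlation ≈ 1.0). Per-region
  standardization fixes Σᵢ‖x̃ᵢ‖² = nM within each group, so the *group mean*
  distance is nearly invariant: covariance heterogeneity widens the distance
  *dispersion* (heavy right tail) but barely moves the mean. Even patients
  drawn from fully idiosyncratic low-rank correlation structures shift the
  mean by only a few percent while the within-group SD grows several-fold,
  leaving the pooled t small.
- Under the null the same sum constraint makes distances weakly negatively
  dependent, so the pooled t is strongly conservative (null rejection rate
  near 0 at the 5% level rather than 5%).

Interpretation: a large t on real data reflects distributional differences
beyond pure covariance heterogeneity of a standardized Gaussian generator
(e.g. outlying thickness values). The package reports the statistic as
defined; these calibration notes bound what a synthetic Gaussian cohort can
show.

## Power analysis

`power_sample_size(d, α, power)` returns the smallest even total n (two
equal groups) whose exact two-sided two-sample t-test power (noncentral t)
reaches the target, found by bisection on the per-group size. For d = 0.5,
α = 0.05, power = 0.8 this gives 128 (64 per group); the statsmodels solver
and the normal approximation 2(z₀.₉₇₅ + z₀.₈)²/d² agree within rounding.

## Top differential edges

Per-edge counts of patients with a Bonferroni-significant deviation; the
shared-edge rule keeps edges significant in at least
max(2, round_half_away(fraction × n_patients)) patients — 4 of 89 at the
default 5% — sorted by descending count, ties by descending mean |z|, then
canonical (row-major upper-triangle) edge order. The pipeline falls back to
the 32 most frequently altered edges when no edge meets the rule, so
downstream stages stay runnable at realistic effect sizes (see the Z
calibration note above).

## Symptom prediction

Random-forest regression (500 trees by default) under repeated nested CV:
outer folds provide held-out predictions; an inner grid search over features
per split {⌈p/3⌉, ⌈√p⌉, p} and minimum leaf size {1, 5} selects the model by
inner-CV MSE; repeats reshuffle all folds from a seeded RNG
(`SeedSequence`-derived, one stream per repeat). Predictions for a patient
come only from folds where the patient was held out (verified by a
target-poisoning test). Reported: per-repeat and pooled MAE/MSE, and Pearson
r (with p) between repeat-averaged held-out predictions and observed scores;
r is NaN-flagged when either side is constant. The feature matrix is one
column per top edge (that patient's Z on that edge); a `mean_feature_mode`
flag collapses the features to their per-patient mean across edges for the
alternative reading of "mean Z-scores of the top edges" as a single
aggregate feature.

Forests approximate smooth signals with piecewise constants: on a noiseless
linear target the cross-validated ceiling is r ≈ 0.93 and MAE ≈ 0.3 SD;
with targets at construction R² = 0.5 the achievable r is ≈ 0.65–0.70
(bounded by √0.5 ≈ 0.71).

## Subtyping

Ward's minimum-variance linkage on Euclidean distances (the Ward.D2
convention, scipy implementation), tree cut to k clusters; deterministic for
fixed input. k is chosen by majority vote over k = 2…6 of five classical
validity indices — silhouette, Calinski–Harabasz, Davies–Bouldin (lower
better), Dunn, Hubert–Levin C-index (lower better) — an extensible registry;
ties break toward the smallest k. Features are not standardized before
clustering (edge Z-scores already share a scale). Stability: patients are
resampled with replacement (default n = 1000), the resample reclustered at
the same k, each original cluster restricted to the resampled subjects is
matched to the bootstrap cluster maximizing the Jaccard coefficient
(greedy, clusters may share a best match), and the per-cluster mean over
bootstraps is reported with > 0.6 flagged stable. Subtype contrasts (defined
for exactly two subtypes with ≥ 2 members each): per-edge pooled t with
Benjamini–Hochberg FDR across edges; continuous clinical variables by pooled
t, sex by Pearson χ² (uncorrected by default, Yates optional); per-edge
two-way ANOVA (subgroup, sex, interaction; type-II sums of squares) with
simple-effects t-tests within each sex only when the interaction is
significant.

## Annotation

The seed set of an edge list is the union of its endpoints. Relative
distribution: %RD(network) = 100 × Σ_seed overlap(region, network) /
Σ_seed region_size; with a partition overlap table the %RD sums to 100. Term
annotation: per term, the coactivation ratio is the mean activation over
seed regions divided by the mean over all regions; the null resamples
equal-size region sets without replacement (default 1000 permutations), and
p = (1 + #{null ≥ observed}) / (1 + n_perm) — never zero, reproducible from
the seed. The null treats regions as exchangeable; spatial autocorrelation
of real activation maps is not preserved, which can make real-data p-values
optimistic. The network table and the term matrix are inputs (synthetic
stand-ins ship for tests); curating real activation databases is out of
scope.

## Synthetic cohorts

Controls: multivariate normal with a block-constant base correlation
(defaults: M = 148, 4 blocks, r = 0.3 within, 0 between — coarse lobe-scale
covariance) on a thickness scale of 2.5 ± 0.25 mm; means/SDs do not affect
correlation-based statistics but keep fixtures realistic. Patients: the base
correlation with subtype-specific edge shifts (largest-remainder
apportionment of subtype fractions; shifts leaving [−1, 1] are spec errors;
shifts breaking positive semidefiniteness are projected back by eigenvalue
clipping and diagonal rescaling). Subject-specific covariance heterogeneity
(`subject_corr_mix` = w) draws patient k from (1 − w)·C + w·R_k with R_k a
random rank-3 sample correlation matrix — a convex mixture, hence a valid
correlation matrix with no projection loss. Symptom scores:
intercept + Σ w_e·(x̃ᵢx̃ⱼ − C_e) + Gaussian noise over designated edges
(exactly linear in the generative deviations at zero noise), floored at 0;
the default intercept (63.6) and noise keep the floor inactive. Demographics
are drawn independently of subtype, so subtype contrasts on demographics are
null by construction.

What the generator does *not* emulate: spatially smooth atlas geometry,
site/scanner effects, non-Gaussian thickness distributions, and
mean-thickness group differences — so passing tests demonstrate the
statistical machinery, not neurobiological validity on real data.

## Problem sizes and numerical choices

The test suite and acceptance script use the study-scale conditions
(n = 89 + 89, M = 148) for the closed-form and planted-recovery checks, and
scaled-down sizes elsewhere: null calibration with 200 patients (plus 2000
patients at M = 8 for the shape test), heterogeneity null over 200 seeds at
M = 40, nested CV at n = 120 with 5×5 folds × 3 repeats and reduced forests,
and bootstrap stability at 200 resamples. Master seeds derive all stage
seeds via `numpy.random.SeedSequence`; identical seeds reproduce every
output bit-for-bit. Ties, degenerate inputs and boundary conventions:
strict Bonferroni inequality, round-half-away share threshold floored at 2,
smallest-k tie-break in index voting, degenerate-edge exclusion from the
test count, NaN-flagged r for constant targets, and collected (not
first-fail) config validation errors.
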