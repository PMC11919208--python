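# idscn — individualized differential structural covariance networks

`idscn` implements an individualized brain-network analysis for case–control
morphometry studies, aimed at researchers who have regional cortical-thickness
tables (e.g. FreeSurfer `aparcstats2table` exports over the 148-region
Destrieux parcellation) for a patient group and a reference control group,
and who want *per-patient* network statistics rather than a single
group-level contrast.

## The method

**Reference and perturbed networks.** The structural covariance network
(SCN) of the controls is the region × region Pearson correlation matrix of
cortical thickness across the n control subjects (rSCN). For each patient
*k*, a perturbed network pSCN(k) is recomputed over the n + 1 group formed
by the controls plus that patient. The patient's individualized differential
SCN is the edge-wise Z-score

    Z_e = ΔSCN_e / [(1 − rSCN_e²) / (n − 1)],    ΔSCN = pSCN − rSCN,

with two-sided p-values from the standard normal and Bonferroni correction
over the M(M−1)/2 edges (10,878 for M = 148). Negative Z means the patient
weakens that covariance edge relative to controls.

**Downstream stages.**

- *Heterogeneity*: each subject's individualized network is the jackknife
  pseudovalue n·C − (n−1)·C₋ᵢ of the group correlation matrix; per-subject
  deviation is the Euclidean distance to the group network over the upper
  triangle, and groups are compared by a pooled two-sample t-test with
  Cohen's d. A noncentral-t power routine reproduces standard two-sample
  designs (d = 0.5, α = 0.05, power 0.8 → 128 participants).
- *Top differential edges*: edges Bonferroni-significant in at least 5% of
  patients (round-half-away, floored at 2; 4 of 89) become the feature set.
- *Symptom prediction*: a random-forest regressor under repeated nested
  cross-validation (10-fold inner and outer, 10 repeats by default) predicts
  symptom severity (CAPS) from the top-edge Z features; MAE, MSE and the
  Pearson r between held-out predictions and observed scores are reported.
- *Subtyping*: Ward minimum-variance clustering on Euclidean distances over
  the Z features; the number of clusters is chosen by majority vote of
  validity indices (silhouette, Calinski–Harabasz, Davies–Bouldin, Dunn,
  C-index) over k = 2…6; cluster robustness is the mean bootstrap Jaccard
  coefficient (n = 1000, > 0.6 considered stable); subtypes are contrasted
  edge-wise (t-test with Benjamini–Hochberg FDR), clinically (t / χ²), and
  for subgroup × sex interactions (two-way ANOVA with simple effects).
- *Annotation*: the seed regions of an edge set are mapped onto seven
  canonical networks by voxel overlap (relative distribution, %RD) and onto
  cognitive terms by a coactivation ratio tested against size-matched random
  region sets (permutation p, add-one estimator).

A built-in synthetic-cohort generator (`idscn.simulate`) draws controls from
a block-structured multivariate normal on a realistic thickness scale
(2.5 ± 0.25 mm) and patients from subtype-specific edge-perturbed
covariances, with symptom scores coupled to the perturbed edges — so the
whole pipeline is testable without access to MRI data.

## Worked example

```python
import numpy as np
from idscn import CohortSpec, IDSCN, WardSubtyper, generate_cohort, tally_and_select

spec = CohortSpec(
    n_controls=89, n_patients=89, n_regions=148,
    subtype_fractions=(34 / 89, 55 / 89),
    perturbed_edges=(
        tuple((i, 40 + i, 0.6) for i in range(8)),     # subtype 1
        tuple((80 + i, 120 + i, -0.6) for i in range(8)),  # subtype 2
    ),
    seed=7,
)
controls, patients, clinical, truth = generate_cohort(spec)

model = IDSCN(alpha=0.05).fit_thickness(controls)
results = model.results_for(patients)
print(model.edge_index_.n_edges)            # 10878
tally = tally_and_select(results, n_patients=89)
print(tally.threshold)                      # 4  (>= 5% of 89 patients)

edges = [(i, j) for group in spec.perturbed_edges for (i, j, _) in group]
cols = [model.edge_index_.linear_index(i, j) for i, j in edges]
Z = model.transform(patients.values)[:, cols]
print(np.round(Z[truth == 0, :8].mean(), 2))   # 0.71: shifted edges show up
print(np.round(Z[truth == 1, :8].mean(), 2))   # 0.06: other subtype does not

subtyper = WardSubtyper(n_boot=200, random_state=1).fit(Z)
print(subtyper.k_, np.bincount(subtyper.labels_)[1:])  # 2 [46 43]
```

This prints `10878`, `4`, a mean Z of `0.71` on a subtype's own perturbed
edges versus `0.06` for the other subtype, and a 2-cluster Ward solution
with mean bootstrap Jaccard 0.67/0.61.
A single patient's perturbation of one edge moves Z by roughly the size of
the implanted correlation shift, with unit-scale patient-to-patient noise —
so subtype structure is visible in the Z features while individual edges
reach Bonferroni significance only for extreme deviations.

The same pipeline runs from the command line:

```bash
idscn power --effect-d 0.5               # -> 128
idscn simulate --spec cohort.yaml --out cohort/
idscn run --config run.yaml --out results/
```

`idscn run` writes per-stage TSV/JSON reports plus a manifest
(`manifest.json`) with the config hash, seed, library versions and per-stage
wall time; identical config + seed reproduces every table bit-for-bit.

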