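# stratakit

Robust multi-view unsupervised patient stratification for mixed-type
clinical tables.

## The problem

In complex diseases, patients with similar outcomes can have different
underlying pathophysiology, and a single clustering of a clinical cohort
is rarely trustworthy: the result depends on how collinear variable panels
are summarised, which dissimilarity and clustering algorithm are used, and
how many clusters are requested. `stratakit` is for epidemiologists and
translational researchers who want to know which patient subgroups in a
cohort are *real* — i.e. which survive changes of analysis parameters and
resampling of patients — and whether there is more than one defensible way
to stratify the same population.

## The method

Given a patients × features table **X** (binary, categorical and numeric
columns; missing values allowed), the pipeline runs three steps:

1. **Data complexity reduction.** Build a dendrogram over the encoded
   variables with average linkage on dissimilarity 1 − |r| (pairwise
   Pearson correlation). Cut it at every depth d = 1…V−2; at depth d the
   variables fall into d+1 groups, and each group is replaced by its
   leading principal component. This yields V−2 candidate *embeddings*
   X₍d₎ ∈ ℝ^(n×(d+1)) — one view of the cohort per plausible grouping of
   collinear variables.
2. **Stratification sweep.** Cluster every embedding under four
   distance/method combinations — (a) correlation + k-means,
   (b) correlation + hierarchical, (c) Gower + k-medoids (PAM),
   (d) Gower + hierarchical — choosing k ∈ {2,…,6} by majority vote of
   the WB-ratio, Dunn index and average silhouette width. Each
   (embedding × combination) cell emits a candidate stratification
   `cuts_{combo}_{depth}`; 30 input features give 28 embeddings and 112
   candidates.
3. **Robustness and consensus.** Discard candidates whose weakest cluster
   has mean bootstrap Jaccard recovery below 0.85. Compare the survivors
   pairwise with the pair-counting Jaccard index
   J = n₁₁/(n₁₁+n₁₀+n₀₁), group them by complete-linkage agglomeration at
   a similarity threshold (default 0.7), and report each group's centroid
   member as a representative. The cohort may admit none, one, or several
   robust stratifications.

With missing data, the sweep runs on each of m chained-equations
imputations and the per-cell results are consensed: modal k, a patient ×
patient co-clustering frequency matrix, and a final hierarchical cut of
that matrix under correlation distance. See `docs/methods.md` for the
full model description, parameter meanings and limitations.

## Worked example

Simulate a structured cohort (two latent subgroups, two collinear blocks
of four variables, cluster means four within-cluster SDs apart), run the
pipeline, and validate the representative against the held-out truth:

```sh
stratakit simulate --n 120 --k-true 2 --block 4:0.8:4.0 --block 4:0.8:4.0 \
    --seed 1 --out cohort
stratakit run --input cohort_data.csv --id-column sample \
    --n-boot 30 --seed 1 --out run
```

```
scenario: complete
embeddings: 6
candidate stratifications: 24 (24 evaluated)
robust after bootstrap: 20
groups at threshold 0.7: 4
  representative cuts_c_1 (11 members)
  representative cuts_b_4 (5 members)
  ...
```

Eight encoded features give 6 embeddings and 6 × 4 = 24 candidates; 20
survive the bootstrap filter, and at threshold 0.7 they collapse into a
few groups, the largest represented by `cuts_c_1` (Gower + k-medoids on
the depth-1 embedding). Validating that representative:

```sh
stratakit validate --run-dir run --labels cohort_labels.csv \
    --positive-label 1 --name cuts_c_1
```

```json
{
  "stratification": "cuts_c_1",
  "sensitivity": 0.9833,
  "specificity": 1.0,
  "confusion": {"TP": 59, "FP": 0, "TN": 60, "FN": 1}
}
```

The representative recovers the planted structure: 119 of 120 patients on
the correct side. `stratakit regroup --run-dir run --threshold 0.9`
re-groups the stored Jaccard matrix at a stricter threshold without any
re-clustering, and `stratakit run --depths 2,5 ...` restricts the sweep to
a subset of dendrogram depths for exploratory work.

The same workflow is available as a library (`create_study`,
`run_pipeline`, `res_stratification`, `validate_stratification`, ...), and
cohorts with missing values are handled transparently (`--m` controls the
number of internal imputations).

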