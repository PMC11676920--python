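# Methods

`stratakit` implements an unsupervised patient-stratification pipeline for
mixed-type clinical tables. Its premise is that a single clustering of a
clinical cohort is rarely trustworthy: results depend on how collinear
variable panels are summarised, which dissimilarity is used, which
clustering algorithm is run, and how many clusters are requested. The
pipeline therefore sweeps a structured space of analysis choices, discards
solutions that do not survive resampling, and reports the small number of
genuinely distinct, robust stratifications that remain.

## Input model and encoding

The input is a patients × features table with binary, categorical and
numeric columns and optional missing values. Feature kinds are inferred
(≤2 distinct observed values → binary; non-numeric → categorical;
otherwise numeric) with a user override that always wins. Categorical
features with L levels expand to L 0/1 indicator columns; binary features
are recoded into a **single** 0/1 column rather than two complementary
indicators. Two indicator columns for one binary feature would be
perfectly anticorrelated and would always be merged by the variable
dendrogram anyway; handling collinearity is the dendrogram's job, so the
encoder avoids manufacturing it. A missing raw cell propagates missingness
to every encoded column it produces. Numeric columns are standardised to
zero mean and unit variance (observed cells only) before any correlation
or PCA computation, because the pipeline's distances and projections are
scale-sensitive and clinical tables mix units.

A held-out label column, when supplied, is removed before encoding and is
only ever touched by the validation functions.

## Step 1 — data complexity reduction

A dendrogram over the **variables** is built with average linkage on
dissimilarity `1 − |r|`, where `r` is the pairwise-complete Pearson
correlation between encoded columns. Absolute correlation is used so that
inversely coded variants of the same measurement group together. For a
table with V encoded columns the tree is cut at depths 1…V−2, where the
cut at depth d has exactly d+1 variable groups and cuts are nested across
depths. Each group is replaced by the leading principal component of its
standardised columns (singleton groups pass through unchanged), giving one
patients × (d+1) embedding per depth — V−2 embeddings in total, e.g. 28
embeddings from 30 features. Optionally the smallest set of components
reaching a cumulative explained-variance target ρ can be retained per
group instead of exactly one. Component signs are fixed by requiring a
non-negative loading on the group's first member, so reruns and parallel
workers agree exactly.

The depth convention (depth d ⇔ d+1 groups, d ≤ V−2) is recorded in each
embedding's provenance. The dissimilarity, linkage and retention rule are
this package's documented defaults; nothing in the method depends on them
beyond "group collinear variables, then project".

## Step 2 — stratification sweep

Each embedding is clustered under four distance/method combinations,
labelled `a`–`d`: correlation distance with k-means (`a`), correlation
distance with hierarchical clustering (`b`), Gower distance with
k-medoids/PAM (`c`), and Gower distance with hierarchical clustering
(`d`). Correlation distance between patients is `1 − r` on row profiles;
Gower distance on the all-numeric embeddings is the range-normalised mean
absolute difference. Hierarchical clustering uses average linkage for both
combos — uniform and configurable. Because k-means needs a coordinate
space rather than a dissimilarity, combo `a` runs Euclidean k-means on
row-standardised patient profiles (each row centred and scaled), the
standard reconciliation of k-means with correlation geometry; its
validation indices are still computed on the true correlation-distance
matrix. k-means uses 25 seeded restarts per cell. PAM is BUILD+SWAP,
with exact enumeration of medoid sets whenever C(n, k) ≤ 3000, where local
search could otherwise stall in a local optimum.

For each (embedding, combo) cell, k is swept over 2…6 (k_max clipped to
n−1) and three internal indices are computed per k from the cell's
dissimilarity matrix: the WB-ratio (mean within- over mean
between-cluster dissimilarity; lower is better; defined as 0 when no
within pairs exist), the Dunn index (minimum single-link separation over
maximum cluster diameter; +∞ when all clusters are points), and the
average silhouette width (patients in singleton clusters score 0). Each
index votes for its best k and the majority wins, ties resolving to the
smallest k — a deliberately conservative rule, since the three indices are
not on a common scale and averaging them would be arbitrary. A k that is
geometrically infeasible on a given embedding (fewer distinct patient
profiles than clusters) is skipped; a cell where no k is feasible, or
where the distance itself is undefined (e.g. a zero-variance patient
profile under correlation), is emitted as a *flagged* candidate so the
sweep never aborts. The sweep emits exactly |embeddings| × 4 candidates
named `cuts_{combo}_{depth}`.

## Step 3 — robustness and consensus

**Population-based robustness.** Each candidate is re-derived on
bootstrap resamples of the cohort (patients drawn with replacement,
re-clustered with the candidate's own combo and k). Each original cluster
is matched to its best-overlapping bootstrap cluster by set Jaccard over
the distinct resampled patients — the clusterwise-stability convention of
the cluster-bootstrap literature — and scored by its mean over
replicates. The candidate's stability is the **minimum** over clusters (a
stratification is only as stable as its weakest cluster; `mean` is
available as a config option), and candidates with stability below 0.85
are excluded (the threshold is inclusive: exactly 0.85 survives). Default
100 replicates, seeded per candidate.

**Parameter-based robustness.** Surviving candidates are compared with the
pair-counting Jaccard index — over all patient pairs, pairs co-clustered
in both partitions divided by pairs co-clustered in at least one — which
is invariant to cluster relabelling and to differing k. Complete-linkage
agglomeration on `1 − J`, cut at height `1 − threshold` (default
threshold 0.7), yields groups in which *every* within-group pair meets the
threshold. Each group's representative is the member with the highest
mean similarity to the others (ties by name). Groups of size 1 are
suppressed by default: one stratification with no parameter-robust sibling
is weak evidence. Because grouping is monotone in the threshold,
`regroup` re-derives groups at any threshold from the stored matrix
without re-clustering; the recommended practice is to start near 0.9 and
lower the threshold gradually.

## Missing data

With missing values, the variable dendrogram is computed **once** from the
original incomplete table (pairwise-complete correlations, minimum overlap
3 observations per pair), so depth semantics are identical across
imputations. The table is completed m times — internally via scikit-learn's
chained-equations imputer (`IterativeImputer` with posterior sampling;
observed cells are preserved exactly and indicator columns are clipped to
[0, 1]), or by accepting m externally imputed complete copies. Default
m = 5. The sweep runs per imputation; then, per (depth, combo) cell: the
consensus k is the mode of the m chosen k's (ties to the smallest), each
imputation is re-clustered at that k reusing its own embedding, and a
co-clustering matrix records the fraction of imputations in which each
patient pair shares a cluster (entries are exact multiples of 1/m). The
cell's final stratification is hierarchical clustering (average linkage)
of the co-clustering rows under correlation distance, cut at the consensus
k — taking correlation between co-clustering profiles rather than using
`1 − frequency` directly as the distance, per the definition of the final
score. With m = 1 this reduces exactly to the complete-data pipeline.
Bootstrap stability in this scenario re-clusters resampled rows of the
co-clustering matrix, since that matrix is the substrate from which the
final stratification is derived.

## Determinism and parallelism

All randomness flows from one root seed through `numpy` `SeedSequence`
spawn keys addressed by (stage, depth, combo, k, replicate, imputation) —
never by execution order — so results are bit-identical for any worker
count. Parallelism (joblib) is applied at the axes where cells are
independent: (depth × combo) cells in the sweep, candidates in the
bootstrap, imputations in the missing-data scenario. The run digest
(SHA-256 over the canonical serialisation of assignments, stabilities and
groups) makes invariance checkable. There is no resume/checkpoint
facility; a run recomputes from scratch (a known limitation).

## Synthetic cohorts

The generator produces what the pipeline assumes: latent patient clusters,
collinear variable blocks, mixed types, MCAR missingness. Each numeric
block follows a one-factor model, `x = μ_cluster + √ρ·f + √(1−ρ)·ε`, so
within-cluster variance is exactly 1, the within-block correlation is
exactly ρ given cluster, and the cluster-mean spacing is expressed in
within-cluster SD units. This makes a single principal component per
block the *correct* summary, i.e. the generator's structure is the one the
reduction step is designed for. Categorical features are quantile-binned
cluster-informed latent scores. MCAR holes use exact counts
(`round(fraction × n)` per column) rather than Bernoulli draws, so tests
are not flaky. The generator does not emulate: informative missingness
(MAR/MNAR), outliers and heavy tails, nested or longitudinal structure,
or unbalanced cluster sizes — conclusions from passing tests are
correspondingly limited to exchangeable-row tables with roughly elliptical
subgroups.

The standard structured test cohort is n = 300 with three blocks of five
variables, within-block correlation 0.8 (a realistic level for a clinical
panel measuring one construct), and separation 4 SD between the two
cluster means; the matching null sets separation and correlation to 0.
The behavioural test suite runs the bootstrap with 30 replicates (the
package default is 100) and the end-to-end checks use cohorts of 80–300
patients; these problem sizes are the package's own choices for its test
fixtures.

## Numerical notes and edge cases

* Dissimilarities are symmetrised and clipped at 0; diagonals forced to 0.
* Correlation distance rejects zero-variance patient rows explicitly.
* Gower ignores zero-range components (averaging over usable ones).
* `fcluster(..., criterion="maxclust")` can return fewer than k clusters
  under tied heights; this surfaces as an infeasible k, not a crash.
* WB-ratio degenerate cases: no within pairs → 0; zero between-cluster
  dissimilarity → 0 with a warning.
* A constant co-clustering row (a patient equally similar to everyone)
  aborts the consensus cut with a "degenerate consensus" error.
* Pair-free partition pairs (both all-singletons) have Jaccard 1.

## Known limitations

* Validation is strictly binary (sensitivity/specificity with the
  majority-class rule); multi-class labels are rejected rather than
  reduced one-vs-rest.
* The method space is fixed to the four distance/method combinations; no
  density-based, spectral or model-based clustering.
* Embeddings are strictly linear (group-wise PCA).
* Internal imputation treats encoded indicator columns as continuous in
  [0, 1] rather than imputing categories generatively.
* No automatic Jaccard-threshold selection; the threshold sweep is manual
  by design.
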