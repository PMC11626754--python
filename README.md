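# climtax

A two-level cluster taxonomy linking **school climate** to **school injury
patterns**, for epidemiologists and school-health analysts working with
EMS injury surveillance joined to ministry climate surveys.

The analysis answers: *do schools with different social climates see
different kinds of injuries?* It proceeds in two stages, treating the
clusters of each stage as latent classes:

1. **Climate patterns.** School-year climate vectors — six questionnaire
   items x = (closeness, efforts, violence, satisfaction, parents, GPF),
   0–100 scores plus a violence count — are screened by correlation-matrix
   PCA (keep items with |loading| > 0.5 on PC1/PC2), z-scored and
   partitioned by k-means. Cluster counts k = 2…8 are compared with a
   spherical Gaussian-mixture BIC (smaller is better) and silhouette; each
   cluster c is profiled by native-scale centroids and Z-scores
   Z_cj = (x̄_cj − x̄_j)/s_j, which order clusters from "good" to "bad"
   climate.
2. **Injury sub-patterns.** Injury cases inherit their school-year's
   cluster (same-year match, falling back to the school's most recent
   earlier climate record). Within each cluster, cases split into two
   sub-clusters by a k-prototypes objective on mixed variables
   Σ‖xᵢ−μ‖² + γ·Σ(categorical mismatches) over age, gender and five injury
   descriptors. The ten leaf sub-clusters are compared with the
   Heterogeneous Euclidean-Overlap Metric, HEOM(x,y) = √Σₐ dₐ², with
   0/1 overlap for nominal and range-normalised distance for numeric
   attributes.

The real datasets behind this design are not public, so the package ships
a synthetic-data generator (`climtax.synthetic`) that plants a known
two-level structure at matching sample sizes and lets every stage be
validated by recovery (adjusted Rand index) against ground truth.

## Worked example

```sh
climtax run --synthetic --out runs/demo --seed 1
```

runs the full pipeline on the default synthetic study (363 schools,
2013–2019, ~10,600 injury cases) and writes every intermediate as CSV plus
a `manifest.json`. The same thing in Python:

```python
from climtax import PipelineConfig, default_config, run_pipeline, recovery_scores

cfg = PipelineConfig(synthetic=default_config(seed=1), seed=1, out_dir="runs/demo")
result = run_pipeline(cfg)
print(result.kcurve.table)        # k, BIC, silhouette for k = 2..8
print(recovery_scores(result))    # ARI vs the planted labels
```

prints (numbers produced by this code at seed 1):

```
   k        bic  silhouette       sse
0  2  30302.142       0.364  6773.827
1  3  27222.283       0.384  4848.862
2  4  24820.315       0.389  3495.524
3  5  21673.100       0.421  2528.936
4  6  22138.836       0.309  2406.122
5  7  22437.099       0.286  2325.083
6  8  22725.357       0.263  2244.383
{'level1_ari': 0.9748, 'level2_ari': 0.882, ...}
```

The BIC attains its minimum at the planted k = 5 (the curve's value at
k = 5 is what justifies stopping there), the silhouette at k = 5 is ≈ 0.42
("fair" separation), and the recovered taxonomy agrees with the planted
one at ARI 0.97 (climate patterns) and 0.88 (injury sub-patterns). The run
directory contains the Table-style artifacts: `climate_profile.csv`
(centroids with Z-scores per cluster), `subcluster_profile_cluster*.csv`
(counts with one-decimal percents per sub-cluster),
`heom_distance_matrix.csv` (symmetric 10×10, zero diagonal) and
per-variable scatter exports against GPF.

Reading real CSVs instead: `climtax run --climate climate.csv
--injuries injuries.csv --out runs/real` (column schemas are the
`CLIMATE_COLUMNS` / `INJURY_COLUMNS` lists in `climtax.synthetic`;
`climtax simulate --out data/` writes conforming examples).

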