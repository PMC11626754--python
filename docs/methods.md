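# Methods

## The two-level taxonomy

`climtax` implements a two-stage cluster analysis that links a school's
social climate to the pattern of injuries its pupils sustain.

**Level 1 — climate patterns.** The unit is the school-year climate vector
of six questionnaire-derived items: teacher–student closeness, efforts
involved, violence cases, teachers' satisfaction, parents' involvement and
general positive feeling (GPF). All items are 0–100 scores except the
violence count. Items are first screened by PCA on the correlation matrix:
an item is retained when |loading| — its correlation with one of the first
two components — strictly exceeds 0.5. Retained items are z-scored and
partitioned by k-means (Lloyd iterations, k-means++ seeding, best of
`n_init` runs). Candidate cluster counts k = 2…8 are compared by a
spherical shared-variance Gaussian-mixture BIC and by the mean silhouette;
the final k is a configuration input (default 5) because cluster-count
choice ultimately rests on interpretability, which we do not automate.
Each cluster is profiled on the native scale with Z-scores

    Z_cj = (centroid_cj − overall mean_j) / overall sd_j,

which place clusters on a good-to-poor climate spectrum. Clusters are
renumbered deterministically by descending GPF centroid (cluster 1 = best
climate).

**Integration.** Every injury case joins the climate record of its school
and calendar year; when that year is missing the school's most recent
*earlier* record is used (surveillance data habitually lag), and cases with
no same-or-earlier record are flagged unmatched and excluded from
clustering but kept in descriptive output. A lenient flag
(`allow_later_years`) borrows the earliest later record instead. Matched
cases inherit their school-year's cluster; cluster profiles are
case-weighted (each case contributes its climate vector), so per-variable
count-weighted Z-scores sum to ~0 by construction.

**Level 2 — injury sub-patterns.** Within each climate cluster, cases are
partitioned into k₂ = 2 sub-clusters on mixed variables — age group
(numeric, standardized) plus six categorical descriptors (gender, event
place, event term, anatomic place, injury cause, injury type) — by a
k-prototypes-style alternating optimisation:

    cost = Σᵢ ‖xᵢ − μ_c(i)‖² + γ · Σᵢ #{categorical mismatches to prototype}.

Numeric prototype entries are cluster means, categorical entries are modes
(ties broken toward the lexicographically smallest label), and the
objective is asserted non-increasing across iterations. A one-hot +
Euclidean k-means variant (`method="onehot"`, mismatch scaling √(γ/2)) is
available for comparison.

**Why γ = 3.0.** With a single standardized numeric among six categoricals,
small γ hands the objective to the numeric: splitting a roughly Gaussian
standardized variable at its median saves ~0.64 squared units per case
(1 − 2/π of its variance), regardless of any categorical structure, whereas
a categorical-structure split saves γ·ΔM per case with ΔM (the reduction in
expected mismatches) typically 0.3–0.7 for contrasts of the strength seen
in this kind of surveillance data. The degenerate age split therefore wins
whenever γ ≲ 0.64/ΔM ≈ 2. The default γ = 3.0 keeps the descriptors in
charge with margin; it is configurable, and the brute-force optimality
tests hold for any γ.

**Leaf distances.** The ten leaf sub-clusters (5 × 2) are compared with the
Heterogeneous Euclidean-Overlap Metric: per attribute, nominal values
contribute 0/1 overlap, numeric values |x−y|/(max−min) with ranges observed
over the full matched dataset, missing values contribute 1, and the per-
attribute terms combine as a Euclidean norm — so complete in-range vectors
satisfy 0 ≤ HEOM ≤ √p. Two aggregations are provided: distance between
per-cluster representatives (numeric mean / nominal mode; the default) and
the mean pairwise member distance (subsampled with a fixed seed above
`pair_sample_limit` pairs). Representative-mode distances are bounded by
√7 ≈ 2.65 for the seven default attributes; reported distances in the
source literature exceed this bound, so the aggregation used there is
under-specified and we make no attempt to match printed distance values.

## The synthetic study conditions

The surveillance datasets this method targets are not public, so the
package ships a generator with planted two-level structure; its defaults
*are* the study conditions used by the tests and the acceptance script.

* 363 schools over 2013–2019, climate reported in a given year with
  probability 0.8 (every school keeps ≥ 1 year, so the fallback join is
  exercised); injuries per school-year ~ Poisson(4.27), giving ~10,600
  cases.
* Each school draws one of five climate classes (weights proportional to
  the published per-cluster case counts). Bounded items come from truncated
  normals on [0, 100] around the class centroid (centroids copied from the
  published five-pattern table); violence from a normal truncated at 0.
* Within-class sd defaults to **0.5 × the per-item between-class sd** of
  the configured centroids. This (a) equalises standardized within-class
  variance across items, matching the spherical-cluster assumption under
  which the BIC is computed, and (b) plants a minimum pairwise class
  separation of ≈ 4.4 within-class sd units. Uniform native noise instead
  concentrates within-class variance on the items with least between-class
  spread after standardization, and the BIC then (correctly, for what it is
  asked) keeps paying for extra clusters that split the dominant axis.
* Each case draws a latent sub-class given its school's class (mixing
  weights from the published sub-cluster sizes), then descriptors from
  per-leaf categorical tables and age/hour from per-leaf normals. The leaf
  tables are the published cross-tabulation columns **sharpened by a
  temperature exponent T = 2.0** (p ↦ p^T, renormalised). The published
  column contrasts alone are not Bayes-separable at the accuracy the
  recovery tests demand (an exact-likelihood classifier reaches ARI only
  ~0.53–0.63 against labels planted from the raw columns); T = 2.0 is the
  smallest grid value whose Bayes-oracle ARI is ≥ 0.90 in every class,
  leaving room for a mode-prototype clusterer that sits below the Bayes
  bound. The qualitative contrasts (girl-dominated vs boy-dominated
  sub-clusters, yard/break vs classroom/unreported, game vs slipping) are
  preserved.
* Ground-truth labels (school → class, case → leaf) are returned so
  recovery is scored with the adjusted Rand index. Level-1 ARI compares
  matched cases' recovered cluster with the planted class; level-2 ARI is
  the case-weighted mean, over planted classes, of the ARI between planted
  sub-class and recovered leaf label within that class.

What the generator does **not** emulate: year-to-year autocorrelation of a
school's climate (years are independent draws), within-school correlation
of injury sub-classes (cases are i.i.d. given the class), school calendars
(event dates are uniform over the year), repeat injuries by the same child,
and any demographic structure. Passing recovery tests therefore show that
the pipeline recovers cleanly separated planted structure at realistic
sample sizes — not that real climate patterns are this separable (the
published silhouette ~0.45 suggests they are not).

## Numerical conventions

* k-means: relative SSE tolerance 1e-8, ≤ 300 iterations, `n_init` 25
  (10 in some tests), SSE asserted non-increasing; empty-cluster collapse
  re-seeds the run (counted); nearest-centroid ties take the lowest cluster
  index. On instances with n ≤ 12 the implementation attains the
  exhaustive-search optimum (tested).
* BIC: σ̂² = SSE/(d·(n−k)); lnL = Σⱼ nⱼ·ln(nⱼ/n) − (n·d/2)·ln(2πσ̂²)
  − d·(n−k)/2; parameters p = k·d + k; BIC = −2·lnL + p·ln(n). Any
  spherical-Gaussian variant shifts values by data-independent constants
  and preserves the ranking across k; σ̂² is floored at machine-tiny for
  degenerate perfect fits.
* Silhouette: Euclidean on the standardized matrix; units in singleton
  clusters score 0.
* Descriptives: sample sd (n−1); 95% CI = mean ± 1.96·sd/√n (normal
  approximation — n is in the thousands; a t-quantile variant sits behind
  `ci="t"`); quartiles by linear interpolation between closest ranks;
  skewness is bias-corrected G1 (0 for constant vectors); percentages are
  half-up rounded to one decimal; missing values are excluded from valid N
  and reported separately.
* PCA retention uses a strict inequality at the threshold; ties at exactly
  0.5 are excluded. Loading signs are indeterminate; retention is invariant
  under sign flips. Missing rows are dropped listwise.
* Mode and representative ties break toward the lexicographically smallest
  category; missing values are ignored in representatives unless all values
  are missing.
* All randomness flows from a single integer seed per entry point
  (generator, model fits, pair subsampling); identical configuration + seed
  reproduces byte-identical CSV/JSON artifacts.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full default study
(363 schools, ~10,600 cases) for recovery and pipeline-shape checks, a
20-seed BIC scan at full climate size, and exhaustive-search comparisons at
n ≤ 12. A reduced study (60 schools, ~1,200 cases) backs the faster unit
tests. These sizes were chosen to match the reference conditions where the
claim depends on them and to stay small where it does not.

## Known limitations

* The BIC favours the planted k only when within-cluster standardized
  dispersion is roughly isotropic; on strongly anisotropic real data the
  scan is advisory (the published analysis likewise reports monotone BIC
  curves and chose k = 5 on interpretability).
* k-prototypes is a local optimiser; with 25 starts on ~10³ cases the
  attained objective is near-optimal in practice but unguaranteed.
* The HEOM leaf distances depend on the aggregation mode; only relative
  comparisons within one mode are meaningful.
* Integration assumes stable school identifiers across years; mergers and
  renumbering are out of scope.
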