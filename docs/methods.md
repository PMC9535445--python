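# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not establish.

## The generic-meals procedure

The pipeline assumes a weighed food diary: participants record, per day and
per self-labelled eating occasion, the foods eaten and their weights, and a
food-composition table supplies per-100 g nutrient amounts. The analysis
proceeds in the fixed order validate → group foods → assemble and score
meals → cluster meals per occasion category → derive generic meals →
substitute → compare intakes. Supplements and energy-free foods are excluded
at the start and stay excluded throughout: the NRF9.3 score is defined per
100 kcal, so energy-free items cannot be scored, and keeping the exclusion
global keeps the original and generic data sets commensurable.

### Food grouping

Foods are clustered within food-pyramid shelves, not globally, so the
derived groups stay interpretable against existing dietary guidance. The
features are the 12 NRF9.3 nutrients per 100 kcal, z-standardized within the
shelf (no external convention fixes the standardization population;
within-shelf is the choice consistent with per-shelf clustering). A constant
feature column is set to zero with a warning rather than dropped, so feature
indices stay stable. k-means runs with 25 restarts, initial centers drawn
uniformly from the data points (delegated to scikit-learn's Lloyd
implementation; a brute-force partition enumeration serves as the oracle in
tests at n ≤ 8).

The cluster count is a majority vote. Eleven internal validity indices are
implemented, every one defined purely from a dissimilarity matrix and a
label vector so the same battery serves both k-means (Euclidean distances on
features) and PAM (Gower matrix): silhouette, Calinski–Harabasz, Dunn,
C-index, McClain–Rao, point-biserial, Xie–Beni and Davies–Bouldin in medoid
form, a WB-ratio (k·W/B, minimized), Ball–Hall (largest drop of W/k) and
Hartigan's rule (smallest k with H(k) ≤ 10). Within-cluster dispersion W is
computed from pairwise distances (W_c = Σ_{i<j∈c} d²/n_c), which equals the
within-cluster sum of squares for Euclidean input. Ties in the vote go to
the smaller k (parsimony). If the winning partition contains a cluster
smaller than `min_cluster_size` (default 4 foods, matching the rejection of
2–3-food clusters that motivated the fallback), the next-most-voted k is
tried, exhausting candidates before reverting to the raw winner with a
warning. For meal clustering the size fallback is disabled by default
(`min_cluster_size=1`): no such rule is reported for the meal stage, and
small meal clusters are handled downstream by the portion fallback.

The vote is not infallible: across a 12-seed sweep at the default synthetic
conditions it over-split one true cluster once (16 groups instead of 15,
shelf ARI 0.93). This mirrors the instability that motivated the original
small-cluster fallback and is the expected behavior of index batteries on
borderline data.

### NRF9.3

Per nutrient, the score contribution is min(100, amount per 100 kcal as % of
its daily reference intake); the nine encourage contributions are summed and
the three limit contributions subtracted, bounding the score to [−300, 900].
Reference intakes are configuration, not constants: the shipped defaults are
EU 1169/2011 Annex XIII values with fiber 25 g and added sugars 50 g
(EFSA-derived; the regulation lists neither), and the table in force is
printed into the run log. Zero-energy meals — possible only if energy-free
foods are retained by policy — receive score 0 with a flag so they remain
clusterable. %TEI uses fat 9, protein 4, carbohydrate 4, alcohol 7 kcal/g,
overridable (e.g., the UK 3.75 kcal/g carbohydrate convention).

### Meal clustering

Meal features are the NRF9.3 score plus 15 binary group-presence
indicators; the signature is a set, so two foods of one group count once.
Gower dissimilarity averages 16 per-feature terms: |Δscore| divided by the
within-category observed score range (clamped to 1) and symmetric 0/1
mismatch per binary. Joint absence counts as agreement — for meals, not
containing a food group is informative. All 16 features are weighted
equally.

PAM is the classic two-phase k-medoids: greedy BUILD, then SWAP steps
applying the best cost-reducing (medoid, candidate) exchange until none
exists, ties broken toward the smaller index pair. Single-start BUILD+SWAP
is a local search and demonstrably settles in 1-swap-local optima on roughly
10–15% of small unstructured dissimilarity matrices (the same behavior is
observed in the long-standing R reference implementation). Because the
package's contract includes exact agreement with exhaustive medoid search on
small instances, `pam` augments the BUILD start with 16 seeded
random-restart SWAP descents and keeps the best solution; the result is
deterministic given the matrix and seed, and matches the brute-force optimum
on 200/200 random Gower instances (n ≤ 12, k ≤ 3) for both dense and sparse
indicator distributions. The restarts add a constant factor (~17×) to a
stage that remains a few seconds per category at desk scale.

Categories with fewer than k_min meals are kept as a single cluster;
categories with at most k_min + 1 meals are fitted at k_min directly, since
no index can discriminate when k ≥ n.

### Generic meals

Outlier removal is sequential: first Tukey fences (Q1 − 1.5·IQR, Q3 +
1.5·IQR, both tails) on total meal energy within the cluster — the standard
reading of an "over 1.5 times the IQR" rule; then, among the survivors,
removal of meals whose total of any micronutrient exceeds 10× the survivors'
mean, with the micronutrient list defaulting to every mg/µg nutrient in the
schema. If either step would empty the cluster it is skipped with a warning.
The per-100 g composition is the unweighted mean over kept meals of
(nutrient total × 100/weight): each meal one vote, matching a mean over
individual meals rather than a pooled mass-weighted mean. Portions are the
medians of the 7 contiguous groups of the sorted kept weights, group sizes
as equal as possible with the remainder allocated to the lightest groups;
clusters with fewer than 7 kept meals cycle their weights to fill 7 slots
with a warning (survey-scale clusters are far larger). Descriptions name,
for each group of the modal signature, the most frequent constituent food,
alphabetical on ties.

### Substitution and agreement

Each meal takes its generic meal's composition at the portion nearest its
consumed weight (absolute difference, ties to the smaller portion, extremes
clamped). Mean daily intake divides by the recorded diary length (empty
days count), and %TEI derivatives come from daily energy. The agreement
battery analyses 31 quantities by default (energy in kJ; eight
macronutrients in grams and as %TEI; fourteen further nutrients in amounts).
Quartile boundaries use linear-interpolation sample quantiles with boundary
values assigned upward; Bland–Altman differences are oriented original −
generic and boundary values count as inside the limits; guideline cutoffs
(cutpoints, categories, basis — amount, %TEI, g/kg body weight, or salt
derived from sodium at 2.5 g per 1000 mg) are configuration with documented
EFSA-style defaults. Zero-variance differences are an error in the
elementary operations, but `build_report` first snaps per-quantity vectors
equal within 1e-9 (relative and absolute) to exact equality: in the identity
limit the substitution round-trip leaves ~1e-16 float noise that Cohen's d
would otherwise amplify into arbitrary values. The summary means are
unweighted averages over quantities of |%difference|, Spearman ρ, extreme
disagreement, and guideline agreement (the |·| convention reproduces the
reported survey summary when applied to its printed table).

## Synthetic data

The generator emulates structure, not marginals. Foods: within each shelf,
k* latent centers in the 12-d per-100 kcal feature space with foods drawn
around them (noise SD 1 per feature by default), mapped affinely to amounts
(base · (1 + 0.12 z), floored just above zero) so the latent geometry
carries into the clustered features, and completed into approximately
energy-consistent compositions (energy = 4·protein + 4·carbohydrate + 9·fat
+ 7·alcohol per 100 kcal, fat capped at 80% of the residual budget so the
added-sugars feature cannot collapse). The stated center separation is
defined in SD units of the standardized features the pipeline actually
clusters; because z-standardization includes between-cluster variance, the
achievable standardized separation saturates (≈2 per dimension), so the raw
center scale is calibrated by bisection to the requested value clamped at
97% of that plateau. Default structure is 2/3/2/2/–/2 clusters across the
clustered shelves plus one fats group and three manual groups (15 true
groups), with a handful of energy-free beverages and flagged supplements to
exercise validation.

Diaries: occasion counts per participant-day follow the per-meal-type daily
rates implied by the emulated survey's published totals (≈4.56 occasions per
day); meal templates per category default to that survey's published
per-category generic-meal counts (63 in total); each template has 1–4 core
groups (always present) and up to two optional groups (inclusion probability
0.25), core signatures within a category differing by at least two groups so
templates are identifiable; portions are log-normal per (template, group)
with σ = 0.35; body weights are N(77.5, 16.1²) kg. A zero-noise mode
restricts inclusion probabilities to {0, 1} for exact-recovery experiments.

What passing the synthetic experiments shows: the clustering, selection,
substitution and agreement machinery recovers planted structure and is
numerically correct and calibrated. What it does not show: performance on
real diaries, whose nutrient marginals, food co-occurrence, portion
distributions and meal heterogeneity the generator does not attempt to
reproduce. In particular the synthetic agreement statistics (e.g., mean
|%diff| ≈ 2%, mean ρ ≈ 0.7–0.8 at 100 participants) characterize the
generator's favorable conditions, not expected field performance, and
synthetic daily totals are larger than realistic human intakes because
templates sample food groups uniformly.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale — 100 participants × 4
days end-to-end (~1,850 meals), 25–30 participants for recovery
experiments, 2000 replicates for type-I calibration — chosen so the whole
suite completes in a few minutes on one CPU; the full 1500 × 4 survey scale
is available through the same parameters. All randomness flows from
explicit integer seeds (`numpy.random.default_rng`); PAM, k-selection and
the pipeline are deterministic given (inputs, seed), and the test suite
asserts bit-reproducibility of a full fit.

## Known limitations

- The index battery is a documented 11-index subset, not the 24-index
  compendium used in the emulated analysis; vote outcomes on borderline data
  can differ from any other battery's, and McClain–Rao in particular tends
  to vote the top of the candidate range.
- Cluster memberships of the original survey are not reproducible from its
  published summaries; agreement with that analysis is checked at the level
  of table arithmetic, not cluster identity.
- Out-of-sample assignment of new meals to generic meals (e.g., for a
  meal-based assessment tool) is deliberately not implemented.
- Guideline cutoffs and reference intakes ship as defaults for convenience;
  any substantive use must supply the values appropriate to its population.
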