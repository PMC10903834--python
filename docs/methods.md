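# Methods

This note documents the models, the synthetic data they are validated
against, the numerical choices, and the limits of what the tests show.

## 1. Virtual landscapes and species

**Climate.** Five bioclimatic variables on a regular lon/lat grid (default
0.05°, 5 km per cell): annual mean temperature (°C), mean diurnal range
(°C), temperature seasonality (SD of monthly means), annual precipitation
(mm), precipitation seasonality (CV %). An elevation surface (smooth
Gaussian random field, 0–3 km; lowest ~8 % of cells become sea and define
the land mask) drives realistic covariance: temperature falls at
6.5 °C km⁻¹, precipitation and diurnal range rise with elevation. A
requested collinear pair (default r = 0.85 between temperature seasonality
and annual mean temperature) is engineered exactly by orthogonal blending,
to exercise the collinearity filter. Note the elevation structure alone
already produces |r| ≥ 0.7 pairs (e.g. precipitation vs temperature), as in
real bioclim layers.

**Future scenarios.** Two futures, *moderate* and *severe*, with severe =
2× moderate in every delta component. Each variable's delta field is
`shift + gradient·(mean elev − elev) + pattern_sd·field(x)`: a mean shift,
an optional lowland amplification (default on warming: lowlands warm ~0.4 °C
more per km below mean elevation, mirroring tropical lowland climate
departure), and a smooth spatial pattern (shared across scenarios so the
severe delta is exactly twice the moderate delta cellwise). Moderate
defaults: +1.8 °C mean temperature, +0.35 °C diurnal range, +0.15
seasonality, −160 mm precipitation, +5 CV % precipitation seasonality —
magnitudes in line with mid-century projections for Mesoamerica. Clipping
keeps precipitation variables non-negative.

**Species.** A species is a product of independent Gaussian responses, one
per variable — the standard virtual-species construction. The optimum is
the present-day climate of a randomly drawn seed cell (so present
suitability is exactly 1 there); montane specialists (default half the
pool) are seeded in the top elevation quartile with breadth 0.85 SD per
variable, lowland generalists in the bottom half with 1.3 SD. These
breadths were chosen so that present ranges span ~25–600 cells (prevalence
mostly below 20 %, as for real tropical trees at regional scale) and so the
two futures spread species across all five IUCN categories. The *true
range* is suitability ≥ 0.5 (configurable); the *true range change* per
future scenario is the cell-count ratio, and the truth-implied IUCN
category follows by applying the A3 thresholds to it — an oracle fully
independent of the modeling pipeline. Families are assigned by k-means
clustering of niche optima, so family-level vulnerability contrasts exist.

**Sampling.** Presence-only records are drawn (with replacement, so
duplicates exercise deduplication) from the present true range with
probability ∝ suitability × effort, where effort is a smooth random field
exponentiated by a bias parameter (default 0 = unbiased). A configurable
fraction of records is degraded to genus-level morphospecies.

**What the generator does not emulate:** taxonomic error and synonymy,
coordinate error, spatially structured absence of effort (roads, herbaria),
niche truncation at study-area edges, biotic interactions, and non-Gaussian
(skewed or bimodal) responses. Passing truth-recovery tests therefore shows
the pipeline is *internally* sound, not that real-data inferences inherit
its accuracy.

## 2. Occurrence cleaning

Order: drop records not identified to species → collapse duplicates within
a grid cell (first record kept; half-open cell binning, upper extent edge
assigned to the last cell) → drop species with fewer than 25 unique
presences (boundary kept). Each step appends (families, genera, species,
records) to a provenance log whose record counts must be non-increasing.
All steps are idempotent.

## 3. Variable selection

Pearson correlations on 10,000 random land points (configurable; 2,000 in
the desk-scale pipeline default). Greedy elimination visits pairs in
decreasing |r|; whenever both members of a pair with |r| ≥ 0.7 survive, the
lower-priority variable is dropped. Priority (a stand-in for "most used in
plant distribution modeling"): annual mean temperature > annual
precipitation > diurnal range > temperature seasonality > precipitation
seasonality. Absolute correlation is used deliberately: strong negative
correlations are equally collinear.

## 4. Ensemble SDMs

* Techniques: scikit-learn `HistGradientBoostingClassifier` (boosted
  trees; 80 iterations, depth 3), `RandomForestClassifier` (60 trees,
  min leaf 2), and a maxent-like model implemented as L2-regularized
  logistic regression on standardized linear + quadratic climate features.
  The maxent surrogate is contract-equivalent (suitability in [0, 1],
  smooth unimodal responses), not numerically equivalent to Maxent.
* Presences and background are given equal total class weight, so the
  presence:background ratio does not distort fitted prevalence.
* Each of the 10 replicates per technique draws a fresh stratified 70/30
  split (training share = floor(0.7·n) per class).
* TSS is evaluated on the held-out 30 % at the TSS-maximizing threshold.
  Candidate thresholds are midpoints between consecutive unique scores;
  ties resolve to the smallest, and separable scores give the gap midpoint
  with TSS = 1.
* The ensemble averages replicates with TSS > 0.7 (strict), weighted by
  raw TSS. The binarization threshold is the TSS-maximizing threshold of
  the ensemble's own predictions on the full presence/background set, and
  the same threshold is applied to every scenario of that species.
  Rank-based weighting and per-replicate thresholds were considered and
  rejected for simplicity; both are one-line changes.
* Background default is 10,000 points in the module API; the pipeline's
  desk-scale default is 1,000 shared points on the 60×60 demo grid (~30 %
  of land cells).

Species whose replicates all fail the skill floor are flagged *not
modeled* and excluded downstream — in the 200-species validation run ~3 %
of attempted species, mostly very widespread generalists whose prevalence
caps achievable TSS (a real and well-known presence/background effect).

## 5. Dispersal limitation

`s′ = s · exp(−d/α)` applied to continuous future suitability *before*
binarization, with the threshold unchanged; `d` is grid-Euclidean distance
(km) measured from the occurrence records themselves rather than from the
modeled present range (switchable). α defaults to 100 km, an
e-folding distance consistent with multi-decadal tree migration being slow
relative to climate displacement; because damping only shrinks suitability,
the limited-dispersal range is a subset of the unlimited one for any α > 0,
and α → ∞ recovers the unlimited projection. Sensitivity to α should be
reported with results; the containment property is α-free.

## 6. Threat classification and summaries

IUCN A3 thresholds (30/50/80/100 % projected loss → VU/EN/CR/EX; inclusive
boundaries) are the standard criterion values and fully configurable.
"Threatened" = VU ∪ EN ∪ CR; EX is tracked separately. One consequence
worth remembering: a scenario severe enough to drive a stratum of species
extinct *removes* them from relative vulnerability, which can lower the
threatened proportion where losses are worst (visible in the worked
example).

Relative vulnerability uses present-day modeled richness as the
denominator (configurable to future richness). Ecoregions (synthetic:
contiguous multi-source BFS partitions of the land mask; montane flag =
region mean elevation above the landscape's 75th percentile) are summarized
over occupied pixels, dropping regions with fewer than 30 pixels; family
percentages are reported for all families and for those with more than 30
species. Scenario comparison: Pearson χ² without continuity correction;
Monte-Carlo p from 2,000 fixed-both-margins tables (Patefield sampling),
`p = (1 + #{sim ≥ obs})/(n + 1)`.

## 7. Driver importance

Per-pixel records: relative vulnerability (shrunk off the boundary by
`y′ = (y(n−1) + 0.5)/n`), the five climate deltas, and a locality id
(ecoregion block). Each iteration samples 500 pixels without replacement
and fits all 2⁵ = 32 subsets (including intercept-only) by maximum
likelihood (statsmodels `BetaModel`, logit link; Newton polish on the rare
non-converged fit). Akaike weights are computed over the full candidate
set; `wg` is each variable's summed weight per iteration averaged over
iterations (the alternative best-models-only average is behind
`wg_mode="best"`), `N` counts best-model inclusions. Coefficients are
model-averaged conditionally on inclusion with unconditional standard
errors `√(Σ w̃ₘ(seₘ² + (βₘ − β̄)²))`, averaged across iterations.

With 500 distinct pixels every locality in a sample is effectively a
singleton, so the iteration loop uses the fixed-effects beta regression —
the documented fallback. A Laplace-approximated random-intercept beta
GLMM (`fit_beta_glmm(..., random_intercept=True)`) is provided for grouped
localities and is cross-checked against glmmTMB in the test suite; at the
default grouping (≈10 regions) it is too slow to run 32 × 1,000 times and
the random intercept mainly absorbs regional means without changing the
importance ranking.

## 8. Validation experiments and problem sizes

All experiments run on one CPU; sizes are the package's demo-scale choices.

* **End-to-end recovery** — full pipeline on a 60×60 landscape, 200
  species, 200 presences each, 10 replicates × 3 techniques, 1,000
  background points. Assigned categories are compared with truth-implied
  categories on the unlimited-dispersal scenarios (where truth is
  defined). Seed-1 result: 73 % exact, 95 % within one category, 96 % of
  species modeled (~11 min). Exact agreement is brittle at category
  boundaries by construction (a species with a true loss of 0.79 vs 0.81
  straddles CR), so the within-one-step figure is the more stable summary.
* **Montane concentration** — truth-map experiment with uniform warming
  (0.75× the default shifts, no lowland amplification), narrow montane
  (0.7 SD) vs broad lowland (1.5 SD) niches: montane-flagged ecoregions
  average 1.4–1.9× the lowland mean relative vulnerability, and region
  vulnerability rises with elevation (Spearman ρ > 0). The moderate
  scenario is used because extreme scenarios push montane specialists to
  EX, which the threatened definition excludes.
* **Driver recovery** — vulnerability simulated from a logit-linear beta
  model (φ = 20) in two of the five deltas (positive diurnal-range and
  precipitation effects); 200 iterations × 500 points recover both with
  wg = 1, N = 200/200, correct signs, z ≈ 20.
* **Oracles** — TSS threshold vs 1,000-point brute-force scan (100 random
  sets); dedup vs set-based counting; distance maps vs closed form and
  min-decomposition; Monte-Carlo χ² p within 0.02 of the asymptotic p;
  beta fits vs glmmTMB.

## 9. Known limitations

* Tree-based learners extrapolate as plateaus into novel climates, which
  biases projected losses optimistic; the quadratic maxent-like member
  counteracts this only partially. This is a faithful property of the
  technique family, not an implementation artifact.
* Presence/background TSS penalizes widespread species (background points
  inside the true range count as absences), so the skill floor removes a
  non-random, high-prevalence slice of the flora.
* The dispersal decay constant is ecologically motivated but not fitted;
  only containment and limiting behaviour are invariant to it.
* Grid distances are planar (km-per-cell factor); no geodesic correction,
  no real CRS.
* The synthetic ecoregions are Voronoi-like growth regions, not
  biogeographic units; the montane flag is a threshold on mean elevation.

## 10. Interface scope

The command line exposes the data-producing stages (`simulate`, `prep`,
`select-vars`) and the composed pipeline (`run-all`). Stage-level commands
for the post-fit steps are deliberately absent: they would require
persisting per-species fitted ensembles between invocations, which the
pipeline avoids by streaming species through fitting, projection and
classification in one pass. Those stages are driven through the library
(`EnsembleSDM`, `apply_decay`, `assess_species`, `DriverImportanceModel`),
which is the intended programmatic interface; `run-all` persists every
intermediate table and raster a downstream analysis needs.
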