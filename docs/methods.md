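# Methods

This package implements an ensemble species-distribution-modeling
(SDM) workflow for presence–absence survey data, of the kind used for
wide-ranging marine megafauna such as the whale shark: environmental
predictors on a regular lon/lat raster grid, a large surveyed sample
with very low presence prevalence and strongly clustered effort, a
small supplement of presence-only records from online databases, and
the need to project habitat suitability onto future climate
scenarios.  Because real survey data of this kind cannot be bundled,
every stage is validated on simulated virtual species whose true
environment–suitability relationship is known.

## Spatial conventions

All grids are regular lon/lat (WGS-84 degrees).  Pixel indexing is
row-major and 0-based with the origin at the north-west corner; a
pixel covers a half-open interval `[edge, edge + cell_size)` in
longitude and one `cell_size` of latitude counted down from the
northern edge (the northern edge itself belongs to row 0).  Predictor
values are extracted at pixel centers, never interpolated: occurrence
data are thinned to the pixel, so sub-pixel position carries no
information.  Great-circle distances use the haversine formula on a
sphere of radius 6,371 km.

## Occurrence preparation

Cleaning applies three rules, in order, and logs removals per rule:

1. records outside the **survey buffer** are dropped.  The buffer is
   the union of circles around all surveyed points whose radius is the
   mean pairwise great-circle distance between the *presence* points.
   The anchors are all surveyed points (presences and absences), the
   radius comes from presences only.  Whether such a calibration
   region should be a union of circles or a convex hull is genuinely
   open; the union of circles is implemented because it makes
   membership a pure per-pixel distance test and never includes area
   far from any surveyed point.
2. records with latitude *and* longitude equal to zero are dropped
   (the classic missing-coordinate artifact of aggregated databases);
3. records whose reported coordinate imprecision exceeds 10,000 m —
   the pixel size of a 5 arc-minute grid — are dropped.  The
   inequality is strict: a record at exactly 10,000 m is retained.
   Survey records carry no imprecision field and are exempt.

Thinning keeps at most one record per pixel with presence priority
(any presence in a pixel makes it a presence pixel), drops records
over nodata pixels with a log entry, and yields the pixel-level design
matrix.  Absences are then subsampled uniformly *without* replacement
to a 1:10 presence–absence ratio; sampling with replacement would
duplicate rows and distort every downstream likelihood.  All
presences are always kept; if fewer absences exist than requested,
all are kept with a warning.

## Variable selection and stability

Candidate predictors go through four stages:

1. **Bivariate screen.**  Each variable alone is tested against the
   response with a likelihood-ratio test (chi-square, 1 df) of the
   single-variable logistic model versus the intercept-only model.
   The LRT p-value is the "informativeness" used by later stages
   (ties broken by explained deviance).  The test statistic here is a
   design choice — single-variable GLM screens in the SDM literature
   do not standardize on one statistic — and is flagged as such.
2. **Correlation filter.**  While any pair of surviving variables has
   |Pearson r| > 0.8, the variable with the largest bivariate p among
   those involved in an offending pair is dropped and the remaining
   pairs re-checked.  Dropping the globally least informative
   offender (rather than resolving pairs in a fixed order) resolves
   correlation chains by removing the middle member.
3. **FDR screen.**  Benjamini–Hochberg at q = 0.05 on the surviving
   bivariate p-values (delegated to statsmodels; an independent
   brute-force BH implementation serves as the test oracle).
4. **Stepwise AIC.**  Forward–backward stepwise logistic selection
   starting from the intercept-only model: at each step all single
   additions and removals are scored and the lowest-AIC move is
   applied iff it strictly lowers the current AIC
   (AIC = −2·loglik + 2·k).  Starting from the null model is the
   conservative reading of "forward–backward"; strict improvement
   (ΔAIC > 0) is the stopping rule, since no tolerance is standard.

Logistic fits use a NumPy IRLS core.  On separation (divergent slopes
or non-convergence) the model is automatically refit with a small
ridge penalty on the slopes (1e-3, intercept unpenalized) and flagged;
the reported likelihood is the unpenalized likelihood of the
stabilized coefficients.  Explained deviance is
D² = 1 − residual/null deviance, which for binary logistic models
equals McFadden's pseudo-R² because the saturated log-likelihood is
zero.

Because the 1:10 absence subsample is random, selection is repeated
(default 1,000 times) over independent resamples; subsets are
canonicalized as sorted name tuples and tallied.  The **modal subset**
(ties: highest count, then fewest variables, then lexicographic) is
carried forward together with a representative resampling seed that
reproduces it, so the downstream modeling sample is exactly
recoverable.  Per-repeat seeds are derived from
`SeedSequence(master_seed, spawn_key=(repeat,))`, making the tally
independent of execution order.

## Ensemble algorithms

Four classic SDM algorithms are implemented from first principles;
the remaining families of the classic multi-algorithm ensemble are
adapters over scikit-learn with documented defaults (the ensemble
protocol, not bit-compatibility with any particular implementation,
is the scientific content):

* **glm** — binomial-logit GLM (the IRLS core above).
* **bioclim** — percentile envelope: per variable the query's
  midranked percentile p among training presences gives a tail score
  2·min(p, 1−p); the suitability is the minimum across variables, so
  any variable outside the training range forces 0.
* **domain** — maximum Gower similarity to any training presence,
  ranges taken from the presences.  A zero-range variable contributes
  zero distance where the query matches it and is excluded from the
  mean (with a warning) where it does not.
* **mahalanobis** — squared Mahalanobis distance D² to the presence
  centroid under the presence covariance, mapped to suitability by
  the chi-square survival function with df = number of variables.
  The raw output of distance-based implementations is an unbounded
  distance; the chi-square map is the monotone [0, 1] transform the
  ensemble contract requires, a deviation in kind (not order) from
  distance-reporting implementations.  When presences number fewer
  than 3× the variables, or the covariance is singular, a diagonal
  shrinkage blend (10%) is applied and flagged.

Envelope methods (bioclim, domain, mahalanobis) train on presence
rows only — adding or removing absences cannot change them.
Adapter defaults: cart/rpart = decision trees (depth-limited vs
cost-complexity-pruned), rf = 200-tree random forest,
brt = gradient boosting, svm = RBF SVC with Platt probabilities,
mlp = one hidden layer of 8 units, rbf = random RBF feature map +
logistic regression, fda/mda = linear/quadratic discriminant analysis,
gam = cubic-spline-basis logistic regression, mars = piecewise-linear
spline-basis logistic regression, maxent_like = presence-vs-background
logistic regression on linear + quadratic features (a simple
exponential-family formulation, not full MaxEnt feature classes).
`bioclim_dismo` is an alias of the native bioclim envelope.  Elastic-
net GLM and Maxlike variants are deliberately absent.

## Evaluation and screening

Cross-validation uses repeated stratified subsampling: 10 independent
runs, each reserving ceil(15%) of *each class* for testing.
Stratification is a deliberate choice: unstratified 15% draws from 74
presences would regularly produce presence-free test sets.

* **AUC** is the Mann–Whitney form, P(score_presence > score_absence)
  + ½·P(tie), computed from ranks.
* **TSS** is max over thresholds of sensitivity + specificity − 1,
  with candidate thresholds at every distinct score and every midpoint
  between consecutive distinct scores; ties go to the smallest
  threshold.  The threshold is chosen per run on the test scores.

Algorithms are retained iff mean test AUC ≥ 0.7 **and** mean test
TSS ≥ 0.5 (strict "under" excludes only values below the bounds) and
at most 5% of raw predictions fall outside [−0.01, 1.01] ("largely
outside the unit interval" needs a number; 5% beyond a 1% tolerance
is ours, values within tolerance are clamped).

The **continuous Boyce index** evaluates a final map against
presence-only data: 100 focal values span the background score range,
each centered in a window of width one tenth of that range; per
window P is the share of presence scores inside and E the share of
background scores, and the index is the Spearman rank correlation
(average ranks on ties) of P/E against the focal values.  Windows
with E = 0 are dropped; among the rest, only the first window of each
distinct P/E value enters the correlation (the ecospat convention) —
without this, long runs of tied zero ratios below the occupied score
range drown the rank signal.  Windows are defined on the background
(modeled-region) scores, and the background is restricted to the
buffer.

## Final ensemble and projection

Retained algorithms are refit on the complete modeling dataset (no
test sample held out) and projected onto the current and future
stacks.  The ensemble summary is the per-pixel arithmetic mean
(unweighted — weighting by CV skill is a defensible alternative, but
plain averaging is the baseline convention) and the *sample* variance
(denominator n − 1) across members.  Cells outside the survey buffer
are flagged, not deleted, so full-extent rasters remain writable
while all summaries (Boyce, areal means) use inside cells only.  No
environmental clamping to training ranges is applied: the analysis is
restricted geographically by the buffer, and envelope members return
0 outside their training ranges anyway.

Raster stacks are stored as NetCDF (via xarray) with one variable per
layer plus the nodata mask; occurrence sets as CSV with columns
`lon, lat, detected, source, imprecision_m`.

## The synthetic worlds

`synthetic` generates virtual-species worlds with the statistical
structure of an open-ocean purse-seine survey dataset:

* **Environmental layers** are standardized Gaussian random fields
  (white noise smoothed with a Gaussian kernel of configurable length,
  in cells).  Collinear decoys are built as x′ = ρx + √(1−ρ²)ε, giving
  a controlled pairwise correlation.  A contiguous-blob land mask
  (default 20% of cells) forces every raster operation to handle
  nodata.
* **True suitability** is logistic in a small driver subset.  The
  shipped world uses four drivers (minimum at-depth temperature +,
  surface temperature range −, minimum surface chlorophyll +, maximum
  surface salinity −) with |β| between 0.8 and 1.4 and intercept
  −5.5.  The deep intercept puts suitability in the low-probability
  regime appropriate to a species with ~0.7% survey prevalence; it
  also sets the achievable discrimination (cross-validated GLM AUC
  ≈ 0.85–0.9, D² ≈ 0.3), chosen once to match the regime reported for
  real whale-shark survey data.
* **Survey sampling** draws visit locations from a mixture of
  Gaussian kernels around configurable effort centers (fishing effort
  is spatially clustered, never uniform); detection at a visited cell
  is Bernoulli with the true suitability rescaled so expected
  prevalence under the effort field hits the target (default
  73/10,583 ≈ 0.69%).  Survey coordinates are taken as exact — the
  spatial error structure of shipboard observer positions is unknown,
  and modeling it would add a free parameter nothing downstream could
  check.  Online records are presence-only, drawn proportionally to
  suitability over all water, with lognormal reported imprecision
  (log-mean 7.5, log-sd 1.5 in meters: median ≈ 1.8 km, ~13% beyond
  10 km, so the imprecision filter has real work) and a configurable
  fraction at lon = lat = 0 to exercise the bad-coordinate rule.
* **Future scenarios** are additive/multiplicative perturbations of
  named layers; the shipped config emits 2 horizons × 2 emission
  pathways as warming shifts of +0.3 to +1.8 standard deviations of
  the temperature layers.

What the generator does *not* emulate: ocean dynamics (currents,
fronts, bathymetry), seasonal structure, observation error in
position, imperfect detection, and spatial autocorrelation in the
residual (detections are independent Bernoulli given the smooth
suitability surface).  Passing tests therefore demonstrate that the
pipeline's statistics behave as designed under a correctly specified
logistic world with realistic sampling geometry — not that any real
species obeys such a model.

## Validation studies and problem sizes

* Metric oracles: AUC and max-TSS checked exactly against brute-force
  pair counting and exhaustive threshold search on 1,000 random
  instances; the FDR stage against an independent BH implementation
  on 1,000 random p-vectors.
* Boyce calibration: presences subsampled uniformly from the
  background give a mean index near 0 (|mean| < 0.2 over 100
  replicates); presences concentrated in the top decile give a mean
  index above 0.9 (20 replicates — the index of a single draw
  fluctuates by ±0.03–0.05 because the P/E profile of this
  construction is flat across the top windows).
* Variable recovery: 100 worlds, each with 2 true drivers (β = 2.2,
  −1.9, intercept −5.5) among 12 candidates including decoys
  correlated at ρ = 0.85, surveyed to ≈ 74 presence pixels and
  resampled 200 times at 1:10.  Recovery is counted only when the
  modal subset equals the true pair *exactly*; typical recovery is
  ≈ 70–80% of worlds, with failures split between a decoy narrowly
  out-ranking its driver on that world's fixed presences and a noise
  variable acquiring a persistent spurious association through
  spatial autocorrelation.  Both failure modes are properties of any
  screen of this design, not implementation defects.
* Pipeline endpoint: the shipped 120×120 world, 10,583 survey
  records, 1,000 selection repeats, all 17 algorithms, 10 CV runs.
  The grid and record counts were chosen as the smallest sizes that
  preserve the study's pixel-level structure (≈ 100 presence pixels
  against thousands of absence pixels).

## Known limitations

* Adapters inherit scikit-learn defaults; they are not tuned, and
  their CV ranking on any one world should not be over-read.
* The stepwise search caches fits within one dataset but evaluates
  single moves only; interactions and paired swaps are out of scope.
* The buffer is a union of circles on pixel centers; pixels partially
  inside the radius are classified by their center.
* `PipelineConfig` equality of two runs guarantees identical reports
  only for identical package versions, as adapter internals may
  change across scikit-learn releases.
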