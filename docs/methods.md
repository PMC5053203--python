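# Methods

This note documents the models implemented in `pigscape`, the design of
the synthetic data generator, the numerical choices that matter, and what
the test suite does and does not establish.

## Holder typology

A holder is a household keeping at least one pig.  Two independent
classifications are applied to each census record:

* **Farming system**, from the commercial pig types kept: farrow-to-finish
  requires all three breeding types (boars, sows, piglets) *and*
  fattening pigs; nursery requires all breeding types and no fattening
  pigs; finishing requires fattening pigs only.  Any other combination —
  including native-only holders, since the system typology is defined on
  commercial breeds — is `unclassified`.  Unclassified holders still
  receive a farm scale and appear in all pig-type tallies.
* **Farm scale**, from total head count.  The published bin labels
  overlap at their endpoints ("5–50", "50–500", "500–5000"); we adopt
  half-open intervals [1, 5), [5, 50), [50, 500), [500, 5000), ≥ 5000,
  anchored by the unambiguous statements that smallholders keep fewer
  than 50 head and large-scale farms 50 or more.

Cross-tabulations count pig-type holders once per type kept (a holder
with sows and fattening pigs appears in both type rows), so holder
percentages across types need not sum to 100 %; system rows count whole
farms.  Shares, pigs-per-holder ratios and medians follow directly.  The
compound annual growth rate is `100·((end/start)^(1/n) − 1)` and is
undefined for non-positive endpoints.

## Covariate engineering

All layers live on one planar square grid (no CRS handling; synthetic
layers are born at analysis resolution, default 1 km).

* **Focal mean**: square moving window; a cell's value is the mean of
  valid cells whose centers fall within the window.  The window must be
  at least one cell wide; a one-cell window is the identity.  Missing
  cells are excluded from the numerator and denominator, and a cell whose
  window holds no valid neighbour stays missing.
* **Cost distance**: minimum accumulated travel time to the nearest
  point of interest over 8-connected paths, each step costing the
  center-to-center distance (cell size, or ×√2 diagonally) times the mean
  friction of the two cells.  Friction must be strictly positive; target
  cells are at zero.  The implementation builds the explicit sparse graph
  and runs multi-source Dijkstra (`scipy.sparse.csgraph`); tests verify
  it against an independent graph-library oracle.
* **Transforms**: travel times, elevation and human density enter the
  models as log₁₀(x + 1).  The +1 offset (rather than log₁₀ x) keeps the
  zero travel time at a point of interest, and any zero density, finite;
  it is monotone, so ranks are unchanged.
* **Zonal aggregation**: a cell belongs to the zone containing its
  center (ties to the lowest zone id).  Predictor value per zone is the
  unweighted mean over member cells; boundary cells are not
  area-weighted.  Response densities are totals divided by zone area —
  head/km² for pig types, farms/km² or farms/10 km² (the default
  reporting unit) for the two farm-scale responses.  Zones with no
  holders keep structural-zero densities; zones with no valid predictor
  cells are dropped with a logged warning.

## The random-forest learner

The ensemble learner is implemented from first principles so that its
behaviour is fully specified:

* *n* bootstrap samples of size *n* drawn with replacement, one unpruned
  CART tree per sample; the expected out-of-bag complement is
  1 − (1 − 1/n)ⁿ ≈ 36.8 %.
* At every node, `m_try` candidate variables are sampled without
  replacement (default 4 of 6 in the distribution models) and the best
  split maximizes the reduction in the sum of squared errors.  For a 0/1
  response, minimizing size-weighted Gini impurity is algebraically the
  same criterion (n·gini = 2·SSE), so classification and regression share
  one split search and differ only in scoring (misclassification rate vs
  mean squared error).
* Split candidates are midpoints between consecutive distinct sorted
  values.  Variables are scanned in ascending index order and thresholds
  in ascending order, and a new best is accepted only when it improves
  the gain by more than 1e-12 — so ties resolve deterministically to the
  lowest variable index and lowest threshold.
* Growth stops at purity, when a node has at most `min_node_size`
  samples (5 for regression, 1 for classification, matching common
  defaults for unpruned forests), or when no sampled variable admits a
  split.  If the `m_try` draw at a node happens to contain only constant
  variables the node becomes a leaf; no re-draw is attempted.
* Classification predictions are class-1 vote proportions (probabilities
  in [0, 1]); thresholding is left to the caller.
* Variable importance is primarily the split-selection count (raw and as
  percent of all internal nodes).  Published importance values for this
  kind of analysis can exceed 100, so the exact statistic used elsewhere
  is ambiguous; a permutation importance (mean per-tree OOB error
  increase after permuting one variable within the tree's OOB rows) is
  reported alongside, and *ranks* are the supported comparison surface.
* Determinism: per-tree random streams are spawned from one seed
  sequence; identical data and seed give structurally identical forests.

## The zero-altered two-part model

Census densities are zero-inflated and over-dispersed.  The two-part
model separates occurrence from abundance:

1. a classification forest for presence (density > 0) on all zones;
2. a regression forest for log₁₀(density + 1) on the non-zero zones only
   (at least 10 are required; with fewer the fit is refused naming the
   response).

The parts are combined as the hurdle expectation P(presence) ×
(10^abundance − 1), floored at zero.  The product rule is the default; a
hard-threshold variant (predict the back-transformed abundance where
P ≥ 0.5, else zero) is available via `combination="threshold"`.  No
bias correction is applied for log-scale smearing in the back-transform —
a deliberately conservative choice.  The four conceptual origins of a
zero (structural unsuitability, design, observer and farmer error) are
not distinguished by the model.

Predictions are produced at two scales: per sub-district from
zone-averaged predictors, and per pixel from the raster stack, the pixel
surface being summed back into zones (zone count = Σ cell density × cell
area) for like-for-like evaluation.  Both are evaluated and reported
separately; on the synthetic fixture the direct zonal predictions are
consistently the more accurate, as expected when the model is trained on
zone-level aggregates.

## Goodness of fit, importance tables, partial dependence

COR is the sample Pearson correlation on the density scale (undefined
and flagged as missing for constant vectors).  RMSE is computed on the
same scale and units as the response.  Partial-dependence profiles force
one predictor to each value of a quantile grid (20 points by default;
quantiles are robust to the skew of travel-time layers) in every row of
the evaluation frame and average the model's combined prediction; for
hurdle models the profile is of the product-rule prediction.  The
importance table collects the abundance-part importances for all five
responses, the per-response COR/RMSE at both scales, and the
across-response median per predictor.

## The synthetic generator

The generator is first-class, tested code; it defines the study
conditions under which every end-to-end property is asserted.

**Landscape.**  Spatially autocorrelated fields are produced by smoothing
white noise with a Gaussian kernel (scale 6 cells by default) and
z-scoring.  Elevation is log-normal around ~55 m; cropland proportions
are logistic transforms of smooth fields; the friction surface is
log-normal with a mild elevation penalty.  One capital cell and `n_poi`
provincial capitals are placed at random cells, and the two travel-time
layers are computed from the generated friction via the package's own
cost-distance operation.  Human density follows the urban gradient:
10^(1.8 − 0.8·t + 0.4·noise), with t the min-max-normalized travel time
to the capital.  Its dynamic range (roughly 1.2 decades) is deliberately
moderate: holders are allocated to zones proportionally to
human-density mass, and a much wider range starves remote sub-districts
of holders entirely, replacing the intended presence-driven zeros with
allocation artefacts.  Sub-districts are the discrete Voronoi cells of
random seed points — irregular, administrative-looking, and exactly a
partition of the grid.

**Census.**  Holders are a union of five primary-category
subpopulations (native 35 %, breeding 15 %, fattening 20 %, smallholder
farms 25 %, large-scale farms 5 % of candidates).  Each of `n_holders`
candidates is assigned a zone (proportional to settlement mass), a cell
within the zone (proportional to human density) and a primary category;
it then draws presence from its category's logit-linear model on the
standardized zone-mean predictors and, upon presence, a conditional
count `max(1, round(10^(lp + N(0, sd)) − 1))`.  The count maps onto the
census columns by category: native counts to the native column; breeding
counts split 5/35/60 into boars/sows/piglets (each at least one when the
count allows); fattening counts to the fattening column; smallholder-farm
counts are capped at 49 head (native column) and large-scale-farm counts
floored at 50 (fattening column), so the typology threshold recovers the
farm classes.  All random inputs are pre-drawn as fixed-size arrays, so
changing one category's parameters never perturbs another's draws and a
fixed seed regenerates a bit-identical census.

This union construction was chosen over two rejected alternatives —
deriving farm-scale responses purely from pig-type draws (which leaves
the farm categories without their own recoverable ground truth), and
rescaling pig-type counts to farm-class totals (which breaks the simple
conditional-count contract above).  Its cost is cross-contamination
between responses (a breeding farm of 160 head also counts as one
large-scale farm), which the default parameters keep sign-aligned: the
categories feeding each farm-scale response share its travel-time and
elevation signs.  The category mix over-represents commercial farms
relative to a real national census on purpose, so that all five
responses retain enough signal in a 16-zone fixture.

**Generative defaults.**  Abundance effects encode the contrasted
geography of the system: commercial categories decline with travel times
and elevation and rise with human density and croplands; smallholder
categories rise with travel times and elevation; human density is the
strongest abundance driver for every category, travel time to the
capital second.  Presence models carry the same signs but a different
shape, because occurrence and abundance are distinct processes: the
smallholder-type categories have a steep absence cliff toward the urban
core, while the commercial categories thin gradually toward remote
zones, where low per-holder presence rates in sparsely settled
sub-districts yield zone-level zeros the covariates only weakly predict
(the analogue of false zeros in a census).  Presence intercepts were
calibrated once so the reference fixture (40 × 40 grid, 16 zones, 5000
candidates, seed 20161006) realizes the intended regime: about a
quarter of zone × response cells are zero and every response keeps at
least 10 positive zones.  The recorded ground truth per zone and
category — presence probability, abundance linear predictor, and the
analytic expected density under the untruncated log-normal model —
re-evaluates exactly from the standardized zone covariates, enabling
recovery tests.

**What the generator does not emulate.**  Real road networks and
geography; within-zone covariate heterogeneity of the presence/abundance
processes (the generative models act on zone means, as the zonal
analysis assumes); reporting error; temporal dynamics; realistic
national proportions of farm classes.  Passing tests therefore show that
the pipeline recovers the structure it assumes, at the stated problem
size — not that the model is correct for any particular real census.

## Numerical and evaluation choices

* Problem sizes: the reference fixture uses a 40 × 40 km grid, 16
  sub-districts, 5000 candidate holders and 500-tree forests; unit tests
  use smaller grids and ensembles.  These sizes make the full suite and
  the acceptance script run in minutes on one core while keeping every
  property measurable.
* The hurdle vs single-forest comparison is made at the method level:
  pooled RMSE across the five responses (root of the mean of squared
  per-response RMSEs), both models fitted with identical transform and
  seeds.  At 16 zones the per-response RMSE difference between the two
  is within random-forest ensemble noise (ratios scatter a few percent
  either side of 1), because — unlike the generalized linear models for
  which the zero-altered advantage was originally reported — a single
  flexible forest can itself carve out covariate-separable zero regions.
  The pooled comparison, which favours the two-part model consistently
  across data seeds, is the stable formulation of the claim at this
  problem size; per-response ratios remain available from the acceptance
  script.
* Importance *ranking* tests require predictors that are not mutually
  confounded; on the default landscape, zone-level human density is
  nearly collinear with travel time to the capital (by construction of
  the urban gradient), so attribution between those two specific layers
  is not identifiable at 16 zones and the ranking test uses an
  unconfounded synthetic frame instead.
* Ties and degenerate inputs: split-gain ties go to the lowest variable
  index and threshold; Voronoi and zone-membership ties go to the lowest
  id; constant responses yield root-leaf trees (not errors); constant
  vectors make COR undefined (missing, with a warning).

## Known limitations

* Farm-density truth for the farm-scale responses is only approximately
  the recorded category expectation, because classification operates on
  realized (clipped, rounded) totals; the approximation error is small at
  the default parameters but the recovery tests for those two responses
  are correspondingly looser.
* The selection-count importance is biased toward variables offering
  many distinct split points; the permutation measure partially
  compensates, and only ranks should be interpreted.
* No CRS or reprojection support: all rasters must share one planar
  grid.
* The pixel-scale prediction applies a model trained on zone-aggregated
  predictors to pixel predictors; this is the intended downscaling
  procedure, but it extrapolates whenever pixel values lie outside the
  zone-mean range (forest predictions are bounded by the training
  response, which limits the damage).
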