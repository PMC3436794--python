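# Methods

This note documents the models implemented in `orangsim`, the defaults and
why, the synthetic data the tests run on, and the limits of what passing
tests demonstrate.

## The hurdle species distribution model

Gridded aerial nest counts are strongly zero-augmented: a large share of
cells have no nests at all, both because habitat is unsuitable and because
pseudoabsences are added outside reserves to represent the unsurveyed,
presumably unsuitable landscape. The counts are modelled as a hurdle
process with two separate parts:

* a **binomial part** — probability that the species is present in a cell,
  fit to every row of the dataset (observed cells and pseudoabsences);
* a **Poisson part** — expected nest count contingent on presence, fit to
  presence cells only. Pseudoabsences are excluded here because they carry
  no abundance information. Because the response is the *mean* count over
  repeat surveys it is real-valued; the Poisson deviance
  `2[y ln(y/mu) − (y − mu)]` is evaluated with real y (a quasi-likelihood
  reading), with `y ln(y/mu) := 0` at y = 0.

Each part is a stagewise gradient-boosted ensemble of shallow regression
trees (xgboost backend: `eta` = lr, `max_depth` = tc, `subsample` = bf,
binomial log-loss or Poisson deviance loss). Tuning follows a
cross-validation-deviance protocol:

* **nt selection.** For each of 10 CV folds one staged ensemble is grown to
  the largest nt on the grid and evaluated on the held-out fold at every
  grid value (nt ∈ {10, 35, …} in steps of 25, up to 15000 by default;
  recovery experiments use a reduced 10…1500 grid). D_cv(nt) is the
  across-fold mean held-out deviance; the selected nt is its exact argmin
  (first value on ties). Folds are random, stratified by presence for the
  binomial part (stratification stabilizes D_cv; the assignment is
  seed-recorded).
* **lr × tc search.** lr ∈ {0.01, 0.005, 0.001} × tc ∈ {1, 2, 3} per
  component, bf fixed at 0.7; the winner minimizes D_cv.
* **Simplification.** Per component, the predictor with the lowest relative
  influence (normalized total split gain, the boosting analogue of
  relative influence) is dropped and the component refit, repeating until
  D_cv(simplified) − D_cv(saturated) exceeds the saturated model's D_cv
  standard error. The four variants (saturated / binomial simplified /
  Poisson simplified / both) are tabulated; the returned model takes, per
  component, the lower-D_cv of saturated vs simplified.

**Thresholding and metrics.** Presence probabilities convert to
presence/absence at the MaxSSS threshold (max sensitivity + specificity
over the set of unique predicted probabilities, smallest on ties), which
down-weights pseudoabsences that may not be true absences. Kappa is
reported at the mean of five candidate thresholds — fixed 0.5, observed
prevalence, mean predicted probability, max-Kappa and MaxSSS — the five
most common rules in the thresholding literature (the exact set behind the
"mean threshold over five methods" convention is not standardized; this
choice is documented here once). AUC is the rank statistic; mse and rmpe
(mean absolute error / mean observed) evaluate the Poisson part on
presence cells. Deviance explained is 1 − D_resid/D_null per component;
the pooled value uses the single ratio of summed residual to summed null
deviances across both parts (components are on different deviance scales,
so the pooled number is a summary, not a likelihood quantity).

**Prediction.** The expected-count raster is the Poisson prediction where
the binomial probability ≥ threshold and exactly 0 elsewhere. The
threshold is held fixed across projection years (no re-thresholding rule
exists for projected landscapes). External validation regresses
independent counts on predictions by OLS and by a Huber-weighted robust
linear fit (iterated re-weighted least squares).

## Land-cover change simulation

**Transition estimation.** From two land-cover rasters T years apart
(outside strictly protected areas) the interval matrix is the
row-normalized count matrix; the annual matrix is its 1/T power via
eigendecomposition, small negative entries clipped to zero and rows
renormalized. The decadal-to-annual root is not unique in general; the
principal eigen-branch with clipping is the standard pragmatic choice and
round-trips to the interval matrix within 1e-6 on valid inputs. Classes
absent at T0 get identity rows (with a logged warning).

**Vulnerability.** A random-forest classifier predicts each cell's current
class from the spatial predictors; its per-class membership probabilities
define the cell's *vulnerability to change* (maximum probability of any
class other than the current one) and *target class* (the class achieving
it; ties resolve to the earlier class in the legend order).

**Unprotected land** steps annually: per source class, expected movers to
each destination (annual rate × class count) are integerized by largest
remainder so destination totals match the row's expected total; the cells
that change are the most vulnerable of the class, preferring cells whose
target matches the destination and filling shortfalls by vulnerability
rank. Conversion out of forest is permanent: transitions *into* forest are
suppressed outside reserves (regeneration is a reserve process), so
unprotected forest is non-increasing by construction.

**Reserves** are harvested at a constant state-wide quota (cells/year) set
once from the observed reserve deforestation rate × initial reserve forest
area — harvest independent of remaining forest. Reserves are consumed in
sequence by decreasing mean vulnerability of their remaining forest,
recomputed each year (the alternative — a fixed initial ordering — is
defensible; annual recomputation is this package's documented choice).
Harvested cells become degraded with a regeneration clock; after 60 years
(default) they revert to forest. A single forest class is used for both
primary and regrown forest (no regrowth class). Pre-existing degraded
reserve cells start their clocks at simulation start. SFM reserves are
never harvested and their clocks do not run, so an all-SFM reserve system
is exactly constant; strictly protected areas never transition at all.

## Climate projection

Scenario climate is baseline + anomaly: additive °C for temperature,
multiplicative per cent for wet- (Oct–Mar) and dry-season (Apr–Sep)
precipitation, given at a few epochs (2010/2041/2071/2100 by default) and
interpolated linearly in time between epochs; the first epoch is the
baseline year with zero change, and years beyond the last epoch raise
rather than extrapolate. A novelty mask flags cells pushed outside the
observed per-variable [min, max], with signed exceedance magnitudes;
predictions in novel cells are *not* clamped — the mask is reported
alongside so users can judge extrapolation risk.

## Scenario engine

Four scenarios cross the SFM policy (current reserves only vs all
reserves) with the emissions scenario (reference "Ref", ~+2.5 °C state
mean by 2100, vs stabilization "Pol", ~+1.2 °C). Per year: the dynamic
predictor layers (forest/degraded/mangrove indicators, climate) are
rebuilt from the simulated state, the hurdle model predicts expected
counts, counts convert to nests-per-km A_i by dividing by the transect
length contributing to a cell (default: the cell side length, one
traversing transect — the count→per-km conversion is a free convention and
is configurable), A_i converts to density by the allometric formula above
(defined as 0 at A_i = 0, its continuous limit), and density × cell area
sums to the total population. No dispersal constraint is applied: any cell
crossing the presence threshold is immediately occupied.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any real geography: Gaussian-random-field terrain (smoothed white noise,
kernel width configurable), Euclidean distances to randomly placed
roads/rivers/settlements, rectangular contiguous reserves (~30% of area,
~20% of them under SFM) and strict-protection blocks (~5%), land-cover
classes carved from a smooth suitability field with reserves forced
forest-heavy, lapse-rate temperature and smooth seasonal rainfall. The
true response is logistic (presence) and log-linear (abundance) in the
z-scored predictors — z-scoring makes the coefficient magnitudes
scale-free. Default effects encode the field expectations (presence up
with forest, distance from roads and warmth; abundance up at low
elevation/slope, far from settlements, in forest) with magnitudes that
keep expected counts in the realistic 0–30 range; `strong_signal_config`
doubles all effects for parameter-recovery experiments. Surveys are
straight north–south transects at a configurable spacing (5 km main /
3 km validation convention), a configurable fraction restricted to
reserves, each crossed cell yielding independent
Bernoulli(p) × Poisson(mu) draws per repeat year. The annual land-cover
truth matrix defaults to ~1.2 %/yr forest loss. The number of
pseudoabsences relative to surveyed cells is a free parameter (no
convention exists).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: spatially autocorrelated observation error,
observer or detectability bias in the counts, temporal trends in effort, a
thermal optimum (the truth is monotone in temperature, so on synthetic
data warming can *help*; in a real system temperatures beyond the observed
range may be harmful in ways a monotone truth cannot express), hunting,
dispersal limitation, and real reserve geometry.

## Numerical choices and problem sizes

* Deviance probabilities/means are clamped at 1e-12 to keep degenerate
  predictions finite; threshold scans use exact comparisons with smallest-
  candidate tie-breaks; argmin ties on the D_cv curve take the smallest nt.
* xgboost runs single-threaded with `tree_method="exact"` and fixed seeds,
  making every fit bit-reproducible; the full pipeline manifest hashes are
  stable across reruns.
* Moran's I uses row-standardized queen contiguity by default (rook by
  flag); the "mean local I" resolution diagnostic is the unweighted mean
  of per-cell local values, which equals the global statistic under
  row-standardization. A constant field raises rather than returning NaN.
* Recovery experiments run on 50×50 grids (~2000 modelling cells) with the
  reduced nt grid (10…1500, step 25) and 10 folds; the demo pipeline runs
  a 32×32 grid, nt ≤ 500–1000, 4 scenarios × 91 years. These sizes are the
  package's test-scale defaults; all grids and parameter spaces scale up
  by configuration.

## Known limitations

* The annual matrix root can be invalid (complex/negative) for interval
  matrices far from the identity; clipping-and-renormalizing is then an
  approximation and the round-trip test tolerance (1e-6) will not hold.
* The pooled deviance-explained formula mixes binomial and Poisson scales.
* Kappa's "mean of five thresholds" set is a convention choice; other sets
  give slightly different Kappa.
* The count→A_i conversion (and therefore absolute population totals) is
  conventional; trajectory *comparisons across scenarios* are insensitive
  to its scale only through the power-law exponent 0.980 ≈ 1.
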