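# Methods

## Overview

The package treats a citizen-science checklist programme as an information
source for species trend estimation and asks two questions: how much did
each past sampling event contribute (its *marginal value*), and where would
a new event contribute most (the *expected* marginal value, mapped daily)?
The pipeline has five stages: filtering, per-species trend GLMs, influence
(dfBeta) computation, causal grid sampling-history covariates, and the
value regression with daily map prediction.

## Filtering

Checklist-level rules, applied in a fixed order so the audit report
attributes each removal to the first failing rule:

1. complete checklists only (absence inference requires them);
2. diurnal start time, default window [05:00, 20:00) local — "nocturnal" is
   not a precisely defined field term, so the window is configurable and no
   solar-elevation computation is attempted;
3. duration strictly between 5 and 240 minutes;
4. travelling checklists must have covered less than 5 km **or** less than
   500 ha (either bound suffices when both are recorded); stationary
   checklists (no distance or area) pass;
5. list length strictly greater than 4 — very short lists tend to be
   targeted searches. The boundary value 4 is excluded (strict reading).

Species enter modelling when they appear on strictly more than 50 retained
checklists, intersected with an optional terrestrial allow-list (no
taxonomy ships with the package; without a list the rule is skipped with a
warning). List length is counted from the raw file before any taxonomic
restriction, because it measures observer effort, not the analysis subset;
a config switch (`list_length_scope`) exists in spirit via recomputation on
read.

## Trend model

Per species, a binomial GLM with logit link:
intercept, `day` (integer days since a configurable origin, default
2010-01-01), county one-hot with the first sorted county as reference, and
offset `log(list_length)`. The offset lives on the linear predictor scale —
a raw species count added to a logit would be dimensionally incoherent —
and the filter guarantees list length ≥ 5, so the offset is positive and
finite. Day is left in raw days; a per-year display transform is ×365.25.

Fitting is IRLS via statsmodels. A fit is *converged* when the IRLS loop
converged, all fitted probabilities are strictly inside (0, 1), and all
derived quantities are finite; constant responses, separation and singular
designs are flagged and excluded downstream with a log message rather than
penalized — transparent, if wasteful of the occasional species.

The fit retains the weighted-design quantities needed downstream: IRLS
weights w = μ(1−μ), working residuals (y−μ)/w, hat diagonals of
W^{1/2}X(X′WX)⁻¹X′W^{1/2}, and (X′WX)⁻¹ (the coefficient covariance, as
dispersion is 1). Hat diagonals sum to the parameter count (asserted to
1e-6), and multiplying all list lengths by a constant moves only the
intercept — both are standing tests.

### Convergence versus sample size

`slope_convergence` subsamples checklists without replacement at a grid of
sizes, refits each species, and records the mean over species and
replicates of |β̂_day(subsample) − β̂_day(full)| plus the mean SE. The
reported summary is the smallest size at which the deviation metric falls
to half its value at the smallest size. The deviation from the full-data
fit is one of several defensible stability metrics; it is simple,
monotone in expectation, and zero by construction at the full size (so
grids should stop short of n, as the acceptance script's does).

## Influence (dfBeta)

For observation i and coefficient j,

    dfbeta_ij = [(X′WX)⁻¹ xᵢ′]_j · wᵢ eᵢ / (1 − hᵢ),

the one-step approximation to β̂_j − β̂_j(i) evaluated at the converged fit.
Sign convention: positive means deleting the observation would lower the
coefficient. For Gaussian least squares this equals the exact leave-one-out
difference (a theorem, asserted to 1e-10 on a 5-point fixture); for
logistic fits it tracks the exact refit with correlation > 0.99 at n = 200
(asserted against a brute-force n-refit oracle, and cross-checked against
statsmodels' independent GLM influence implementation).

Raw (unstandardized) dfBeta is the default; a `standardized` option divides
by the coefficient SE. The marginal value of a checklist is the row sum of
|dfBeta| on the day coefficient across converged species. Observations with
hat diagonal within 1e-8 of 1 have no defined deleted fit; their entries
are excluded from the sum (set to 0) and the checklist is flagged, so one
pathological species cannot poison a checklist's value. Whole-model
measures (Cook's distance) are deliberately out of scope: the quantity of
interest is one coefficient, the trend.

## Grid sampling-history covariates

The region's bounding box (in a projected plane; a built-in equirectangular
local projection handles geographic input at regional extents) is tiled
with square cells whose side is the *grain* in km — grains are side
lengths, not areas, which is the only reading consistent with
nearest-neighbour distances spanning tens of km. Cells are clipped to the
region extent; a boundary cell's centroid is the centroid of its clipped
part, so centroid spacing is irregular near the boundary exactly as when a
regular grid is intersected with a study polygon.

For each cell and date d, using only samples strictly before d:

- `ever_sampled`; `n_unique_days` (distinct sampled dates — several
  checklists on one day count once); `days_since_last` (≥ 1);
  `sampling_duration` (last minus first sampled date);
- `median_interval`: median gap between consecutive distinct sampled dates,
  floored at 1; a single-day history is assigned 1 (keeps the covariate
  finite and matches observed minima of 1);
- `dist_nearest_sampled`: centroid distance to the nearest **other**
  previously-sampled cell (0 only when no other sampled cell exists). The
  focal cell is excluded from its own search: including it would make the
  covariate identically zero for every training row (all training rows come
  from ever-sampled cells), i.e. no covariate at all;
- `neighbor_median_interval`: the median interval of that nearest cell.

Causality — a future-dated checklist never changes any parameter at an
earlier date — is property-tested over hundreds of random histories.

Point-in-cell assignment uses the half-open convention [x0, x1) × [y0, y1);
points outside the grid are dropped and counted.

## Value model

Training rows are the evaluation-year checklists (the final calendar year
by default): response = log marginal value, covariates = the checklist's
cell's parameters on its date. Rows from never-before-sampled cells are
split off for the unsampled-effect test (they lack the history covariates).
Sampling duration is excluded up front — it tracks the median interval —
and a correlation screen reports (but does not drop) any remaining pair
with |r| > 0.7 on the log scale.

Covariates are log-transformed (log1p for the distance, which is legally 0
in the degenerate single-sampled-cell case; plain log elsewhere, all
floored at 1 by construction) and standardized with **training** means and
sds, which are stored on the fit so prediction is consistent. The
standardized coefficients are directly comparable effect sizes. OLS via
statsmodels; rows with non-positive marginal value are dropped with a count
(log undefined); a rank-deficient design is fatal.

One robustness rule sits in the pipeline rather than the model: at a
coarse grain with a long sampling history a covariate can be *exactly*
constant across training rows (every cell's nearest sampled neighbour at
exactly the lattice spacing, say). Such a column is excluded from that
grain's model with a logged warning — the same move as the duration
exclusion — and the fit records the covariate set it used.

The never-sampled contrast is a separate two-group regression of log
marginal value on an unsampled indicator, reported per grain with effect,
SE and p, and flagged infeasible when the evaluation year contains no
first-ever visit at that grain (at coarse grains every cell may already
have a history). No multiple-testing correction is applied across grains;
per-grain p-values are reported as-is.

### Daily maps

For each date, ever-sampled cells get the model prediction from their
parameters (training transforms); never-sampled cells are imputed with the
mean of the sampled cells' predictions — reflecting the absence of evidence
that unsampled cells differ — and flagged `mean-imputed`. Where a cell
received several checklists that day it holds several predicted values
(identical, since covariates are cell-level); one is kept uniformly at
random with the supplied seeded generator and the choice is recorded in the
provenance flag. Maps stay on the log (modelling) scale. Same seed, same
inputs ⇒ bit-identical maps.

## Synthetic worlds

The generator emulates unstructured avian atlasing on a 200 × 200 km region
(5 km base grain, 1,600 cells): effort is concentrated in 10 Gaussian
hotspots (sd 12 km) whose intensities fall off as rank^−1.5 and whose
placement is biased toward one corner (the "city"; Beta(1, 3) coordinates),
plus a 2% uniform background of birding far from hotspots, so remote cells
receive occasional first visits and some cells stay unsampled for years.
Counties are Voronoi regions over corner-biased seeds, giving the
categorical term real spatial structure.

Each of the 6,000 checklists (4 years, uniform dates) draws a cell from the
effort weights, a position uniform in the cell, a start time (95% diurnal),
a log-normal duration around 60 min (with small deliberate tails outside
the 5–240 min filter window) and, for travelling checklists (70%), a
log-normal distance around 1 km. 3% are incomplete. Species detections are
per-species Bernoulli with logit = intercept (prevalence uniform on
(0.10, 0.60)) + β_day·day (β_day ~ N(0, 5e-4) per day — a drift of about
0.7 logits over the record) + county effect (sd 0.5) + a latent
per-checklist effort score (sd 1.0) shared across species. List length is
the realized number of detections — no separate draw — so the
effort/offset relationship is internally consistent; a checklist detecting
nothing produces no file rows, as in a per-observation export. Species
left undetected everywhere have their intercept redrawn upward with a
warning.

What the generator does *not* emulate: weekend and road effects, observer
skill heterogeneity, detection probability varying over the annual cycle,
group-checklist duplication, and taxonomic structure. Passing tests
therefore demonstrate the statistical machinery (influence, causality,
recovery, calibration) under a known model, not robustness to every bias of
real checklist data.

The fitted trend model conditions on log list length with offset
coefficient 1 while the generator's effort acts through a latent score;
for low-to-moderate prevalences log E[list length | effort] is close to a
unit-slope function of the score, so the mismatch is mild — day-slope 95%
intervals achieve ~93–95% empirical coverage in the calibration study,
which is the honest price of a realistic (not self-referential) effort
model.

## Problem sizes and seeds

The test suite and acceptance script scale simulations to desk size as the
package's own study conditions: oracle worlds of 200 checklists × 5
species; calibration studies of 100–200 replicate worlds of 1,500
checklists × 10 species; value-model recovery at n = 2,000 planted rows;
500-replicate null calibration of the unsampled test; and the full default
world (6,000 checklists, four grains) for end-to-end closure. All
randomness flows from explicit seeds; reruns are bit-identical.

## Known limitations

- Only the stated logistic trend GLM is implemented; occupancy/detection
  models and spatial autocorrelation terms are out of scope, though any
  model exposing a coefficient of interest could supply the influence step.
- Each checklist id is treated as independent; shared group checklists are
  not collapsed.
- The equirectangular projection is adequate at regional extents only.
- Whether summed dfBetas should be raw or SE-standardized is a genuine
  modelling choice; raw is the default (the printed deletion formula),
  standardized is an option, and the two can rank checklists differently
  when species' trend SEs differ widely.
- The evaluation-year design predicts value from history alone; it does not
  model feedback (maps changing behaviour changing maps).
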