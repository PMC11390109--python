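# Methods

This note documents the models and procedures implemented in flyscape, the
assumptions behind them, the parameters that matter, and the design choices
made where several defensible options existed.

## The statistical core

### Matched-stratum conditional logit

The step-selection function contrasts each observed commuting step with
alternatives available at the same start point and time. For strata *s*
containing one used step and *n* alternatives (51 rows total with the
default *n* = 50), the likelihood is

    L(β) = Π_s  exp(β′x_used,s) / Σ_{j∈s} exp(β′x_j).

The design has ten fixed-effect columns, all on z-scores: `tri`,
`dist_ridge`, `step_length` main effects; `step_length:week`; and the twoand
three-way interactions of each terrain covariate with step length and week
(`tri:step_length`, `tri:week`, `tri:step_length:week`, and the `dist_ridge`
counterparts). A **week main effect is deliberately absent**: week is
constant within a stratum, so stratum conditioning removes it from the
likelihood — its coefficient would be structurally unidentifiable (in the
equivalent Poisson formulation it is absorbed by the stratum intercepts).
The `step_length:week` term is included both because it is a marginal term
of the three-way interactions and because the growth of step-length
preference with age is a quantity of direct interest.

Fitting is damped Newton iteration on the strictly convex negative
log-likelihood with analytic gradient and Hessian and per-stratum
log-sum-exp stabilization. Convergence requires a gradient sup-norm below
1e-6 (max 500 iterations); a coefficient norm above 50 on the z scale is
treated as quasi-separation and raises an error naming the worst covariate.
Standard errors come from the inverse observed information; 95% CIs are
±1.96 SE. At β = 0 every stratum of 51 contributes exactly ln 51, a fact
the tests exploit; the vectorized likelihood is verified against direct
softmax enumeration to 1e-10 and against `survival::clogit` in R.

### Individual random slopes

Individual variation in the response to the two terrain covariates enters
as independent Gaussian random slopes u_g ~ N(0, diag(σ²_tri, σ²_dist)) per
individual g, integrated out by a Laplace approximation: an inner Newton
solve per individual for the penalized mode, an outer L-BFGS-B over (β, log
σ). Profiling the stratum intercepts of the Poisson log-linear
reformulation yields exactly this conditional likelihood, so the estimator
matches the usual Poisson-with-huge-stratum-variance trick without
materializing stratum intercepts. The slope correlation is fixed at zero
(nothing in the analysis requires a correlated structure). Fixed-effect SEs
for the mixed fit are computed from a numerical Hessian at the optimum with
the variance components held at their estimates — they do not propagate
variance-component uncertainty. If the marginal optimization fails, the
fixed-effects fit is returned with a prominent warning recorded on the fit
object. At least five individuals are required; with fewer, the slope
variances are not identifiable and an error instructs the caller to use the
fixed-effects fit.

### Predictive check

The normalized RMSE compares the inverse-logit of the fixed-effects linear
predictor (stratum effects omitted, random effects at zero) with the 0/1
used indicator, normalized by the indicator's observed range (= 1).
Normalizing by the mean or SD of the observations are alternatives; the
range convention keeps the value in [0, 1]. Because the predictor carries
no intercept and one row in 51 is used, values near 0.5 are expected for
weak predictors — the metric is reported as a descriptive diagnostic, not
optimized.

## Terrain metrics

* **TRI** is the mean of |elev(neighbor) − elev(cell)| over the up-to-8
  adjacent cells (edge cells use the neighbors they have; nodata
  propagates). This is the mean-absolute-difference form, not the
  root-sum-of-squares variant.
* **TPI** is elev(cell) minus the mean elevation over cells whose
  center-to-center distance d satisfies inner < d ≤ outer (default 10 m and
  200 m). The annulus is strict-inner/inclusive-outer; at 25 m cells the
  10 m inner radius excludes only the focal cell, which keeps the detected
  ridge lines narrow. Radii are configuration inputs, not re-derived.
* **Ridge lines** are cells whose standardized TPI exceeds +1 SD — the
  ridge class of the standard landform convention. Only this class is
  consumed; the full taxonomy is out of scope.
* **Distance to ridge** is the exact Euclidean distance transform
  (center-to-center, not chamfer), in meters.
* **Aggregation** to the 100 m analysis grid is a nodata-aware block mean;
  the target cell must be an integer multiple of the source cell. Real-mode
  inputs must already be at the resolution intended for metric computation
  (arbitrary-ratio resampling is not implemented).

All four operations are verified against brute-force double-loop oracles.

## Track segmentation

Flight altitude = height above ellipsoid − geoid undulation − ground
elevation, with the DEM sampled at the containing cell. Ground speed is
planar displacement over elapsed time between consecutive fixes (device
speeds are not assumed); the first fix of an individual inherits the second
fix's value.

Behavior classification replaces the bivariate EM-binary-clustering
algorithm with **two independent one-dimensional two-component Gaussian
EMs** (speed, altitude), fitted at the population level. The downstream
analysis consumes only the high-speed/high-altitude corner, which this
simplification preserves; the delimiter and smoothing machinery of the
original algorithm is not reproduced. EM is initialized at the 25th/75th
percentiles, runs to a log-likelihood change below 1e-8 (max 500
iterations), restarts up to 5 times with perturbed initialization on
component collapse, and its likelihood trace is asserted non-decreasing in
tests. A point is "high" only when its posterior strictly exceeds 0.5
(ties resolve low). When a variable's component means are separated by
less than twice the larger SD, a low-separation warning is logged.

Tracks are clustered at native resolution and then subsampled to hourly
(nearest fix within ±10 min of each whole hour — idempotent by
construction). Commuting bouts are maximal runs of consecutive hourly HH
fixes with inter-fix gaps ≤ 75 min ("nonstop"), keeping runs of ≥ 2 points
(≥ 1 h).

## Dispersal

An individual is dispersed at the first inside-radius fix followed by more
than 14 consecutive days without any fix inside the nest radius (7 km
default; per-individual overrides, e.g. 30 km, are supported). Any single
fix inside counts as a recursion. The emigration instant anchors at that
last inside fix — reproducible and conservative. If the absence begins but
the track ends within the 14-day window, the individual is flagged "not
dispersed (insufficient data)"; a final fix with no observations after it
is no evidence of departure. Weeks since emigration are
floor(days/7) + 1; the analysis uses weeks 1–156 (three years).

## Used/available sampling

Movement kernels are fitted on the pooled population: gamma by maximum
likelihood on positive step lengths (zero-length steps cannot enter a gamma
likelihood; more than 50% zeros raises a stationarity error), von Mises
(unit scale) on defined turning angles, with κ capped at 500 for degenerate
angle sets. Turning angles are counter-clockwise positive relative to the
previous step's bearing.

Alternative endpoints share the used step's start point, individual, and
week; their bearings are the previous bearing plus a von Mises turn.
**Bearing context for the first step of a bout** is taken from the
displacement out of the hourly fix immediately preceding the bout (the
entry into the bout) when that fix is within 75 min; this matters because
dropping the context and sampling isotropically measurably attenuates the
terrain coefficients in recovery experiments (directional persistence
correlates with terrain along ridges). Truly context-free steps (track
starts, long gaps) receive uniformly distributed alternative bearings and
enter the model but not kernel fitting. Endpoints outside the terrain
layers or on nodata are redrawn (up to 1000 rounds, then an error); strata
whose *used* endpoint is on nodata are dropped with a warning.

Covariates (TRI and ridge distance at the endpoint from the 100 m layers,
step length, week) are z-transformed with the mean/SD of the full
used+available dataset by default; the constants are stored on the fit for
prediction-time reuse and can be supplied externally (the recovery
experiments supply the generator's frozen world constants so estimates and
truth share a scale). A Pearson correlation screen flags any predictor pair
with |r| ≥ 0.5 (reported, not fatal; in ridged synthetic worlds TRI and
ridge distance are naturally anti-correlated around that level).

A subtlety worth stating: re-fitting a "tentative" gamma kernel to observed
step lengths absorbs the *average* step-length preference into the
availability distribution (for a gamma kernel and a linear length effect
the exponential tilt is exactly another gamma), which shifts the
step-length main effect toward zero while leaving its week interaction
estimable. This is a property of uncorrected empirical availability
kernels, not an estimator defect; the parameter-recovery experiments
therefore draw alternatives from the generator's known kernels, while the
pipeline default remains the data-fitted kernels.

## Energy landscape

Flyability of a cell in week w is the inverse logit of the fixed-effects
predictor at the cell's z-scored terrain, z-scored week, and the z-scored
mean observed step length of week w (weeks with fewer than 5 observed steps
borrow the global mean). Predictions are population-level (random effects
at zero); per-individual maps via the slope modes are available from the
mixed fit. Flyable area counts cells strictly above the threshold
(default 0.7, a configuration input) times 0.01 km² on the 100 m grid.

The weekly area series gets a constrained least-squares logistic fit
A/(1 + exp(−k(t − t0))) with positive A and k. The fit is flagged (not
failed) when the rate is ~0 or the midpoint falls beyond the observed
weeks — the latter means growth has not saturated and the asymptote is
unidentified, which routinely happens on short or shallow series. The fold
change is area(last)/area(first), undefined (flagged) when the first week
has zero area.

Hotspot maps are Gaussian KDEs over flyable-cell centers with Silverman's
rule by default (the scipy covariance-based factor; an isotropic one-cell
kernel replaces it when fewer than three or collinear centers make the
covariance singular). For tractability the centers are subsampled to 5,000
and, on grids above 40,000 cells, the smooth density is evaluated on a
strided subgrid and linearly upsampled before renormalization to unit
integral over the region.

## The synthetic world

The generator exists to make every stage falsifiable by parameter recovery.
Its defaults are the study conditions used throughout the tests and the
acceptance script.

* **Terrain**: a 250 km planar world at 100 m cells; elevation is a base of
  800 m plus 8 Gaussian-profile ridge crests (amplitude ~1200 m, width
  1500 m, random positions/orientations) plus smooth low-frequency noise
  (150 m amplitude, 5 km correlation scale). Coordinates are planar meters
  throughout; no geographic CRS exists in synthetic mode.
* **Sampling schedule**: one fix every 20 min during a 10 h daily activity
  window; 30 pre-emigration days of nest-bound wandering (clamped inside a
  500 m natal radius), then 156 post-emigration weeks (three years, the
  study span).
* **Behavior**: alternating commuting/non-commuting bouts with geometric
  durations (means 3 h and 97 h, i.e. roughly 2–3 commuting hours per
  week, sized so the default population yields a few thousand strata).
  Commuting bouts cannot span the overnight roost: they truncate at the end
  of the activity window, as a nonstop flight bout should. Emigration
  opens with a commuting departure flight so the detected emigration
  instant sits within hours of the true phase switch.
* **Movement and selection**: at each commuting hour the agent draws M =
  300 candidate endpoints (gamma lengths, von Mises turns off the previous
  bearing; uniform bearings at bout starts) and selects one with
  probability ∝ exp(β′z) via the Gumbel-argmax identity. Candidates
  outside the world or on nodata are redrawn. The finite-M softmax
  attenuates coefficients relative to the exponential-tilt limit by
  O(1/M); at M = 300 the attenuation is below measurement noise in
  recovery experiments, while remaining independent of the analysis' 50
  alternatives.
* **Speed/altitude classes**: fixes are interpolated along hourly steps, so
  commuting fix speeds are step_length/3600 s. The default kernel
  (gamma shape 36, scale 1200 m; mean 43.2 km, SD 7.2 km) therefore
  *implies* the commuting speed class N(12, 2) m/s; the non-commuting class
  draws 20-min segment speeds from N(1, 0.5) m/s. Flight altitudes are
  N(300, 80) m (commuting) vs N(20, 15) m (other), plus N(0, 5 m)
  altimetry noise on the ellipsoid height and a constant 48 m geoid
  undulation. The classes are well separated by design so that
  segmentation accuracy (≥ 99%) is attributable to the EM machinery, not
  luck.
* **Scale**: covariates in the selection kernel are z-scored with
  world-level constants frozen at generation time (raster moments for the
  terrain layers, kernel moments for step length, the 1..W week range), so
  `true_beta` has a defined scale the analysis can target. The default
  coefficients follow the qualitative pattern of interest: +0.6 TRI, −0.6
  ridge distance, +0.5 step length, with week interactions −0.15/+0.15
  attenuating the terrain terms (no sign flip across the z-range of weeks)
  and +0.25 strengthening the step-length preference, plus ±0.06 minor
  interaction terms.

### What the generator does not emulate

No meteorology (thermals, wind), so "uplift" exists only through its
topographic proxies; no memory, territoriality, or conspecific avoidance;
no GPS positional error (only altimetry noise); no data gaps or fix
failures; a rectangular world whose boundary truncates long steps (both
simulation and analysis share the truncated availability, but marginal
step-length distributions are slightly compressed relative to the
configured gamma). Passing recovery tests therefore demonstrates that the
estimation machinery is correct under the model's own assumptions — not
that the model is adequate for any particular real dataset.

## Problem sizes and tolerances

The recovery study runs 20 replicate seeds at 20 individuals × 100 weeks
(roughly 2,000–2,600 strata of 51 after segmentation) on one shared
landscape; the landscape-dynamics check and the acceptance script use the
full 156-week span. Brute-force oracle comparisons hold to 1e-10 (likelihood,
gradient) and 1e-9–1e-12 (terrain); kernel-recovery bands are 5% at
n = 10,000. Newton tolerance is 1e-6 on the gradient sup-norm; EM tolerance
1e-8 on the log-likelihood. File round-trips use plain-text ASCII grids at
%.8g precision, which reproduces coefficients to ~1e-3 across a full
pipeline round trip.

## Known limitations

* Real mode expects pre-projected planar inputs (a metric CRS) and a DEM
  already at the desired metric resolution; no reprojection or
  arbitrary-ratio resampling is performed.
* The mixed model's SEs condition on the estimated variance components.
* The logistic growth fit is only as identified as the series allows; flags
  on the fit object must be checked before interpreting its parameters.
* Flyability extrapolates the week covariate beyond the weeks observed in
  sparse datasets (the z-transform is linear, so this is a linear
  extrapolation on the logit scale).
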