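# Methods

`colonytrack` implements the complete analysis chain for ultra-wideband
(UWB) tracking of semi-precocial gull chicks inside a fenced, plot-divided
breeding colony: trajectory cleaning, movement metrics, kernel home ranges,
proximity-based social networks, density covariates, mixed-model inference
and a within-plot node-permutation null — together with a synthetic-data
generator that emulates the study system so that every stage can be
validated end to end without field data.

## Trajectory cleaning

Raw fixes (nominally one per tag per 30 s, spatial accuracy ~0.33 m) pass
three filters, in a fixed order:

1. **Boundary** (`boundary_buffer_m`, default 0.5 m). A fix more than the
   buffer outside the fenced colony boundary is physically impossible and is
   dropped; the buffer absorbs ordinary tag error. This filter runs first so
   impossible positions never anchor the speed pass.
2. **Artifact lines** (`artifact_min_run`, default 3). Receiver artifacts
   occasionally repeat an x-coordinate verbatim, drawing vertical straight
   lines; runs of three or more consecutive fixes with bitwise-identical x
   are removed. Removal is iterated to a fixpoint so the filter is
   idempotent. The run-length criterion and exact equality are deliberate:
   real coordinates essentially never repeat bitwise at 30 s spacing.
3. **Speed** (`speed_max_ms`, default 0.2 m/s — faster than a chick walks).
   A greedy forward pass per tag: the first fix is kept, and each later fix
   is dropped iff its apparent speed from the last *kept* fix exceeds the
   ceiling. Removing the later endpoint of a violating pair is the
   deterministic convention of standard telemetry cleaning; which endpoint
   the original protocol removed is not documented, so this choice is
   config-exposed.

Cleaned tracks are resampled to a regular grid (default 5 min) by taking the
raw fix nearest each grid time within ± half an interval (ties to the
earlier fix). Interpolation is deliberately avoided: it would fabricate
positions, possibly inside territories the chick never entered. Grid times
without a fix are simply omitted, and steps spanning an omitted grid time
contribute nothing downstream.

## Movement activity and repeatability

*Movement activity* is the mean Euclidean distance between successive
5-min-resampled positions over the whole (3-day) tracking period. Daily
summaries use 24 h blocks anchored at each chick's first fix (avoiding
partial first days); the square root is applied after daily averaging.

Consistency across days is *repeatability* (intraclass correlation) from the
Gaussian random-intercept model

    sqrt_step_ij = mu + a_i + e_ij,  a_i ~ N(0, s_a^2),  e_ij ~ N(0, s_e^2),
    R = s_a^2 / (s_a^2 + s_e^2),

fitted by REML. The one-random-intercept model admits a closed-form profile
of the REML criterion over the variance ratio (the classical group-mean
shrinkage transform), so each fit is a one-dimensional optimisation taking
microseconds; the implementation agrees with statsmodels `MixedLM` to
numerical precision (checked in the test suite) and negative variance
estimates are truncated at zero so R stays in [0, 1]. The 95% CI comes from
a parametric bootstrap (default 1000 replicates: simulate from the fitted
model, refit, take percentiles), which is the default behaviour of the
standard repeatability tooling for Gaussian data; a case-resampling
bootstrap is available as an option.

## Home range

Home range is the area of the 95% kernel utilization distribution with the
reference bandwidth

    h_ref = sqrt((var_x + var_y) / 2) * n^(-1/6),

a single scalar bandwidth on both axes, matching the conventional "href" of
the ecology toolchain. The kernel density is evaluated on a 200 x 200 grid
covering the point cloud's bounding box padded by 3 h, normalised to unit
mass; the area is the count of cells above the smallest density threshold
whose cells jointly contain >= 95% of the mass, times the cell area. The
"mass >= level" rule is deterministic and makes area monotone in the level.
Grid size and padding were chosen so the analytic oracle — the 95%
highest-density region of an isotropic bivariate normal, area
pi * 5.991 * sigma^2 — is reproduced within a few percent and halving the
cell size moves the estimate by < 2%. Boundary/fence effects are *not*
kernel-corrected; fence proximity instead enters the models as a covariate.
Home ranges are computed on the resampled fixes.

## Social associations

Association detection runs on the raw, unsampled fixes to maximise the
chance of catching co-occurrences. Timestamps are rounded to the nearest
30 s (half-up; if two fixes of one tag round to the same value the fix
nearest the rounded time wins, ties to the earlier). Two chicks associate
when simultaneously (same rounded timestamp) strictly closer than 0.6 m —
the tags' spatial resolution plus a chick's body envelope. Candidate pairs
come from a per-timestamp k-d tree; exact distances are re-checked so the
strict inequality is honoured, and the whole detector is verified against a
brute-force every-pair oracle by exact set equality.

Events are counted once per unordered pair per rounded timestamp (no
merging into bouts). *Degree* is the number of distinct non-sibling
partners, *strength* the total non-sibling event count; sibling events
(which dominate by an order of magnitude) are reported separately. Both are
proxies: untracked chicks and adults cannot contribute.

## Density and fence covariates

Breeding density is the mean distance from a nest to its three nearest
neighbouring nests (NN3): pre-natal = the chick's origin (laying) nest,
post-natal = its foster (rearing) nest, both against the full nest set. The
network models use a post-natal variant restricted to nests with at least
one tracked chick, since only tracked neighbours can generate associations.
A nest is "near a fence" when strictly closer than a threshold to any fence
segment (colony boundary included, switchable); the threshold is the mean
step distance plus one SD — one typical move carries a chick from nest to
fence — computed from the data by `fence_threshold` (0.91 + 0.41 = 1.32 m
at the study's step statistics).

## Models and inference

Four models relate per-chick responses to sex, age-corrected body size
(OLS residuals of tarsus length on age), pre- and post-natal NN3 and fence
proximity:

| response | transform | family | random effects |
|---|---|---|---|
| movement activity | sqrt | Gaussian | nest in plot |
| home-range area | sqrt | Gaussian | nest in plot |
| degree | — | Poisson | plot |
| strength | log | Gaussian | plot |

The movement/home-range models additionally carry the pre x post NN3
interaction (centred product), dropped when non-significant at alpha 0.05.
Nested Gaussian fits go through statsmodels `MixedLM` (variance
components); term tests are 1-d.f. maximum-likelihood ratio chi-squares.
The nest-in-plot structure for the Gaussian chick-level models reflects the
strong dependence of siblings (movement correlations ~ 0.9); the network
models keep a plot-only random intercept because half the nests contribute
a single chick. Both structures are configurable.

The Poisson mixed model is fitted by maximum likelihood with adaptive
Gauss-Hermite quadrature (mode-recentred, 30 nodes) over the single random
intercept, with Wald z tests; it reproduces lme4 `glmer` (nAGQ = 25)
coefficients to ~1e-5 (cross-checked via Rscript in the test suite).
Zero-strength chicks are excluded (with a log message) before the log
transform; a zero-handling rule is otherwise undefined.

### Node-permutation null

Network-derived responses violate independence, so the network models'
significance is additionally assessed against a node-label permutation
null: the response vector is shuffled among chicks *within each plot*
(equivalently, node labels move on the fixed network; edges and covariates
stay put), the model is refitted, and each term's coefficient recorded.
Defaults are 10 000 permutations. Two summaries are reported: the two-tailed
permutation p with the +1 correction,

    p = (1 + #{|beta_null| >= |beta_obs|}) / (n_perm + 1),

and the flag "observed coefficient outside the central 95% of the null",
which is the classical criterion but has no exact p. Plots with a single
tracked chick contribute no permutation freedom and are logged. Gaussian
refits inside the loop use the fast profiled REML on a fine grid of the
variance ratio (coefficient error from the grid is negligible against the
permutation spread; the observed coefficient is computed by the same grid
engine so observed and null are exactly comparable). Poisson refits use the
quadrature ML per round. The permutation machinery is applied to the
network models by default but accepts any of the models.

`compare_density_classes` checks the density manipulation itself: a 1-d.f.
ML likelihood-ratio chi-square for the HD/LD difference in NN3 with a plot
random intercept. With density class constant within plots, the plot effect
is weakly identified; a single plot per class is flagged.

## Synthetic data

The generator's defaults are the study conditions:

* **Colony**: eight 25 x 34 m (850 m^2) plots in a 4 x 2 grid, mesh fences
  on shared edges and the outer boundary; four HD plots with 43 nests and
  four LD plots with 21. Nests are placed by sequential sampling with a
  hard-core minimum spacing (0.6 m) plus a mild attraction/spacing ladder
  calibrated per plot so the realised class-mean NN3 approaches 2.96 m (HD)
  and 4.78 m (LD); uniform placement alone lands above the HD target
  (Poisson-process geometry), hence the clustering knob.
* **Chicks**: 76 cross-fostered clutches (LD->HD 16, HD->LD 28, LD->LD 22,
  HD->HD 10) decouple pre- from post-natal NN3; 51 tracked nests carry 68
  tracked chicks (17 sibling pairs). Sex is Bernoulli(1/2), tagging age
  uniform on 15-25 d, tarsus linear in age with Gaussian noise.
* **Movement**: each chick is the sum of three zero-mean OU components
  around the foster nest — fast nest-attached jitter (per-30 s persistence
  0.78, stationary SD 0.35 m) plus slow shared-sibling and individual
  excursion processes (stationary SD 0.9 m, time constant 30 min), weighted
  c and sqrt(1 - c^2) by the sibling cohesion c (default 0.9) so the
  marginal variance is cohesion-invariant. All innovation scales carry the
  planted density effect — a linear factor 1 + 0.35 (NN3_post - mean) — and
  log-normal nest/chick/day activity multipliers whose shared components
  are weighted by the cohesion; these drive the sibling correlation of
  movement (~0.94 under defaults) and the dominance of sibling
  associations. Positions reflect at the colony boundary, so it is the
  observation noise, not the truth, that exercises the 0.5 m buffer filter.
* **Observation**: fixes on the 30 s lattice with increments drawn from the
  0.8/0.1/0.1 mixture of 30/60/180 s gaps, plus isotropic Gaussian noise of
  SD 0.263 m per axis — Rayleigh mean error 0.263 sqrt(pi/2) ~ 0.33 m,
  matching the tags. A single Rayleigh scale implies an error SD of
  ~0.17 m, somewhat below the tags' reported spread; the mean, not the SD,
  is matched.

Placing the density effect on the innovation scale is the simplest single
mechanism that moves step lengths and home-range area together, and the
defaults were chosen to land near the study's descriptive statistics (mean
5-min step ~1 m, home ranges of tens of m^2, non-sibling association counts
in the tens). What the generator does *not* emulate: day/night activity
rhythms, aggression-driven avoidance dynamics, adult movement, heavy-tailed
localisation errors and tag dropout. Passing tests therefore demonstrate
estimator correctness and calibration under a plausible movement model, not
ecological validity of any particular parameter value.

Scenarios: `paperlike`/`planted` are the defaults above; `null` zeroes the
planted density slope and the sibling cohesion for type-I-error checks.
Every simulation is deterministic given its seed; the pipeline fans a
global seed out to per-stage seeds by fixed offsets.

## Problem sizes used in the checks

The validation suite runs simulations at reduced temporal resolution where
the full 30 s lattice adds nothing to the question being asked: the
permutation-calibration check uses 500 null datasets of one day at 5-min
fixes with 1000 permutations each (the scenario's covariate structure and
all 68 chicks retained; one colony/chick layout is held fixed across
replicates so the check is conditional on a single design, as is standard
for type-I-error simulations); planted-effect recovery uses 50 full
three-day scenarios at 5-min fixes; the sibling-cohesion check uses two
days at 60 s. The repeatability recovery check simulates the
random-intercept model directly (68 chicks x 3 days, among-SD 0.84,
residual SD 0.537, closed-form ICC 0.710) — the scale at which the field
estimate was obtained.

## Numerical choices and edge cases

* Duplicate (tag, timestamp) fixes: first occurrence kept, count logged.
* Zero elapsed time between distinct same-tag fixes is a data error.
* Timestamps are real-valued seconds since tracking start; ISO-8601 input
  is converted on read. Coordinates are local planar metres.
* NN3 ties at the third neighbour break by nest id; nests with fewer than
  three candidate neighbours (possible for the tracked-only variant in toy
  colonies) get NaN with a warning.
* The KUD threshold rule takes the smallest cell count whose mass reaches
  the level, so `area(level)` is non-decreasing and discretisation-stable.
* Variance ratios are profiled on [0, 1) via rho = lam/(1+lam); boundary
  fits (rho = 0) are accepted and reported as R = 0 / zero variance.
* Permutation p-values use the +1 correction and are therefore never 0.

## Known limitations

* The Gaussian LMM assumes homoscedastic residuals; the planted generator
  is mildly heteroscedastic on the response scale (log-normal multipliers),
  which the sqrt/log transforms largely absorb.
* Degree/strength are proxies censored by tag availability; the generator
  reproduces the censoring only implicitly (untracked chicks simply do not
  exist in the simulation).
* The permutation null conditions on the observed network; it does not
  model uncertainty in association detection itself.
* `compare_density_classes` inherits the weak identification of a plot
  random effect under a plot-constant covariate; its chi-square is best
  read as descriptive confirmation of the manipulation.
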