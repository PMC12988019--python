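# Methods

`routemem` quantifies how faithfully homing pigeons retain collectively
learned routes, and whether pairs retain them better than individuals.  This
note documents the models, the estimator, the synthetic-experiment generator,
and the numerical choices, in enough detail to reproduce or audit any number
the package computes.

## Study design being analysed

Pairs of pigeons are trained by repeated paired releases from two sites
(Stanton Harcourt, 51.7527778, -1.42375; Long Hanbrough, 51.8303056, -1.3915)
to a shared home loft (51.7828602, -1.3173753).  The last three paired
releases of training are GPS-tracked and interspersed with three tracked solo
releases per bird; these tracked paired releases are the *baseline routes*.
Each pair then undergoes one treatment per site: *forgetting* (an eight-week
release-free gap) or *extra training* (nine further paired releases, two solo,
the last three tracked, then a five-week gap).  At memory testing each pair is
released once per site, either as a pair or as two solo birds (randomised,
balanced within treatment and site).

## Track preprocessing

All rules operate on WGS84 geodesic distances (vectorised Vincenty inverse;
at these scales it agrees with Karney-style ellipsoidal geodesics to well
below a millimetre).  In order:

1. **Speed filter** (30 km/h): fixes whose instantaneous speed — geodesic
   displacement from the previous fix over the time gap, computed once on
   the raw track — falls below the threshold are removed.  Cruising pigeons
   fly at 60–80 km/h, so this removes pre-release dawdling and post-landing
   fixes.  Speeds are *not* recomputed iteratively; the operation is a single
   deterministic thresholding.
2. **Homing-segment trimming**: keep fixes from the *final* departure out of
   2 km around the release point through the first entry within 500 m of the
   loft (boundary fixes inclusive).  Tracks that never depart or never reach
   home are excluded with named reasons.
3. **Joined-flight exclusion**: each track is sampled every 30 s and checked
   against fixes of every other same-session track within ±15 s wall-clock;
   any sampled fix within 50 m flags the pair of tracks and both are excluded.
   The ±15 s matching window (half the check interval) is a package choice,
   exposed in `PreprocessParams`; the flag-implies-exclusion rule replaces
   manual map inspection to keep the pipeline deterministic.
4. **Split truncation**: the two tracks of a paired release are compared on a
   common 1 s grid (nearest earlier fix, forward-filled over gaps ≤ 5 s); the
   split time is the earliest moment the birds exceed 150 m separation
   without ever re-establishing ≤ 150 m proximity, and both tracks are cut
   there.  Transient separations that re-converge do not split.

Every exclusion or truncation is written once to an exclusion ledger
(release, bird, rule, detail).

## Response metrics

For a test track `T` and the baseline routes `B_1 … B_k` of its pair and site
(each baseline route pools the preprocessed fixes of the two members of one
tracked paired release, who fly within the 150 m split rule of each other):

* **mean NND** — mean over fixes of `T` of the geodesic distance to the
  nearest fix on any pooled baseline route;
* **2nd-order mean NND** — per-route mean NND, averaged with equal weight
  over the `k` routes (robust to variable `k`); it is never smaller than the
  pooled mean NND;
* **HEI** — beeline distance between first and last fixes over cumulative
  path length, in (0, 1].

At baseline testing time a release is compared only to *previously recorded*
baseline routes (so the first tracked paired release yields no route-memory
observation — only efficiency); at memory testing, to all baselines.  Paired
releases contribute one observation per release: the arithmetic mean of the
two members' raw metric values, transformed afterwards (the transform of the
mean, not the mean of transforms; with coherent paired flights the two are
nearly identical, but the convention is fixed).  Nearest-neighbour distances
are point-to-point, not point-to-segment: at 1 Hz sampling (≈ 18 m fix
spacing) the difference is a few metres and is absorbed in the noise floor,
but it is a known discretisation limitation.

Transforms: `ln(mean NND)`, `ln(2nd-order mean NND)`, and
`ln((1 − HEI)/HEI)` (strictly decreasing in HEI).  Degenerate values, which
arise only in noiseless synthetic fixtures, are floored (NND of 0 m → 1 m)
or clamped (HEI of exactly 1 → 1 − 1e-6) with a log message.

### Exactness of the nearest-neighbour search

Production NND uses a uniform-grid index over coordinates projected onto a
local tangent plane, with candidate pruning justified by two inequalities:
orthogonal projection never increases 3-D chord distance, and the
ellipsoidal geodesic lies within a factor 1.006 of the spherical great-circle
(mean radius) between the same points.  Every candidate that could beat the
chord-nearest point is therefore re-evaluated with the exact ellipsoidal
distance, and the result equals an exhaustive double loop over all point
pairs — asserted to 1e-9 relative tolerance in the tests.

## Multimember mixed model

Each response is analysed with

    response ~ condition * treatment * testing_time + site
               + (1 | individual) [multimember] + (1 | pair)

using treatment (dummy) coding with configurable reference levels.  An
observation from a paired release loads on both member birds with weight 0.5
each (row-normalised multiple membership, matching the averaging of the two
birds' responses; 1/1 weighting is available via `ModelSpec.pair_weight`);
solo observations load on their single bird with weight 1; every observation
loads on its pair with weight 1.  The marginal covariance is

    V = s2_resid I + s2_individual Z1 Z1' + s2_pair Z2 Z2'.

Variance components are estimated by REML: the criterion is profiled over the
residual variance and the fixed effects, leaving a 2-dimensional optimisation
over log variance ratios, solved by Nelder–Mead from three seeded starts
(multi-start guards against boundary traps) with criterion tolerance 1e-10;
ratios below 1e-8 are reported as exact boundary zeros, never raised as
errors.  Each profiled evaluation uses the Woodbury identity on precomputed
cross-products, so it costs O(q^2)–O(q^3) in the number of random-effect
levels q, independent of n.  The reported log-likelihood is recomputed with
a direct dense evaluation at the optimum, which is also what the grid-search
oracle in the tests maximises independently.

Wald tests use t = estimate/SE against the standard normal, with no
denominator-degrees-of-freedom correction (Satterthwaite/Kenward–Roger are
not applied); this slightly understates p-values at small n and is the main
reason the type-I calibration below sits marginally above 5%.  Planned
contrasts (simple effects at chosen factor levels) are obtained by refitting
the identical model with releveled factors; releveling preserves the REML
log-likelihood, and the releveled coefficient equals the contrast-vector
statistic from the original fit — both invariances are asserted in tests.

Residual diagnostics whiten `y − X beta` with the Cholesky factor of the
fitted V and apply a one-sample Kolmogorov–Smirnov test against N(0, 1)
(the estimated-parameter caveat is ignored, as in common practice), plus QQ
data for plotting.

The *better-solo* analysis reduces the table, per metric, to pairs versus the
better member of each pair whose two members were both tested solo (solo
observations matched within pair by release order; the better bird may differ
between metrics, so the reduced tables differ in size across metrics); the
same model is refitted on the reduced table.

## Synthetic experiment generator

The generator is first-class, tested code: it produces the tracks, metadata
and ground-truth ledger that every pipeline stage and the calibration /
recovery studies run on.

**Route memory.** A pair's route at a site is a corridor of 12 interior
waypoints at equal beeline fractions with independent perpendicular Gaussian
offsets (sd 400 m), endpoints fixed at the release point and loft.  After the
treatment gap, each bird retains each interior waypoint independently with
probability 0.6 (forgetting treatment) or 0.9 (extra training); within-pair
retention can be correlated through a shared Gaussian copula latent (default
correlation 0, the regime of interest).  Forgotten waypoints collapse to the
beeline plus perpendicular noise (sd 800 m).  A pair tested together pools
memories waypoint-wise: under the default *distributed* rule a waypoint
survives if either member retains it (averaged if both do, freshly
beeline-perturbed if neither), so the pair's expected retention is
1 − (1 − p)^2; under the alternative *leader* rule the pair flies the
better-retaining member's chain.  With retention 1 the generator is exactly
null: paired and solo memory flights follow identical route distributions.

**Flight realisation.** Flights traverse the waypoint chain at 65 km/h,
sampled at 1 Hz, with three additive disturbance processes:

* *route execution* — each pair and site carries a joint "habit": a smooth
  lateral field along the route (3 sine/cosine harmonics) whose coefficients
  evolve as a random walk that advances only on flights the pair makes
  *together*.  Every release expresses the current habit plus a fresh
  per-release execution field of the same scale (30 m): one shared field when
  the birds fly paired, each bird's own independent field when flown solo.
  The release-free treatment gap adds no joint-habit steps (the habit is
  practice-driven, not calendar-driven; `memory_drift_steps` generalises
  this).  Persistence matters twice over: without it, the minimum-over-k
  structure of the NND metrics produces a steep artificial decline of
  baseline-time NND in the number of available baselines; and if the
  persistent state were expressed unchanged in both solo releases of a pair,
  those two observations would be strongly correlated in a way the model has
  no term for.  Under the joint-habit construction the deviation of any
  flight from its nearest baseline is dominated by one independent fresh
  increment — approximately homoscedastic across cells, uncorrelated across
  releases, and nearly independent of the number of baselines;
* *wobble* — per-flight smooth lateral noise (sd 20 m), shared by the two
  members of a paired release (they fly together);
* *day scale* — a per-release lognormal factor (sd 0.5 on the log scale,
  i.e. roughly ×/÷1.6 day to day) multiplying that flight's whole execution
  deviation (fresh field and wobble).  Release-day conditions are a large,
  well-documented source of variation in homing performance; statistically
  this factor adds the same variance to every cell's log response, which
  keeps the responses close to the homoscedastic normal model the analysis
  assumes;
* *GPS error* — AR(1) per-axis error with stationary sd 15 m and innovation
  correlation 0.98.  Temporal correlation matters: independent 15 m jitter at
  1 Hz would alone imply apparent speeds near 95 km/h, making the 30 km/h
  stationary filter vacuous; real 1 Hz logger error is strongly
  autocorrelated.

Each track is wrapped with a slow pre-release dawdle (~8 km/h, 30 s) and a
loft approach, so the speed filter and trimming always have work to do.
Releases are scheduled 240 s apart on a per-session clock, giving join
detection genuine overlapping windows.  Everything is driven by keyed
`SeedSequence` streams: identical configs are bit-reproducible, and
per-pair/site streams are order-independent.

**Ground truth.** The ledger records, per memory release, the retained-mask
of each bird and the noise-free mean NND between the realised flown route
(waypoints + drift field, no wobble/GPS) and the pair's realised baseline
routes, subsampled at 5 s.  The per-treatment *generating effect* is the mean
log noise-free NND of solo memory releases minus paired ones.  Recovery is
assessed against this realised truth: the waypoint-retention draws are part
of the generated effect, not estimation error, so the model SE is expected to
cover `estimate − truth`, not the across-replicate spread of estimates.

**What the generator does not emulate.** No wind, landmarks, flocking
dynamics, leadership hierarchies, or learning curves during training; GPS
error is stationary; the corridor is fixed over training.  Passing tests
therefore demonstrate that the pipeline and estimator behave correctly on
data with the assumed statistical structure — not that real pigeon data meet
those assumptions.  One known divergence from the study's qualitative
summary: with the default retentions (0.6 vs 0.9) the extra-training
pair-vs-solo difference is attenuated in absolute NND but remains comparable
on the log scale and is often statistically detectable, whereas the study
observed a non-significant trend; retentions closer to 1 in the
extra-training arm would reproduce non-significance, but the defaults are
kept as the package's stated conditions.

## Calibration and power (computed by tests and `scripts/acceptance.py`)

* Under the null generator, the memory-testing solo-vs-paired Wald contrast
  on log mean NND is checked to reject at 5% ± 2% at alpha = 0.05 across
  1000 simulated experiments (14 pairs each).  The residual inflation above
  exactly 5% comes from the normal reference (no df correction) and mild
  heteroscedasticity between baseline and memory observations.
* Under the default forgetting effect, across 200 replicates: the contrast
  estimate is positive (solo further from baseline than pairs) in ≥ 90% of
  replicates, covers the ledger's realised generating effect within 2 SE in
  ≥ 90%, and the testing-time × condition interaction is detected with power
  > 50% (empirically near 100% at the default effect size).

Problem sizes in the acceptance script (250 null replicates, 120 effect
replicates) are the package's reporting defaults; the test suite uses 1000
and 200 respectively.

## Numerical choices and edge cases

* Ellipsoidal WGS84 geodesics everywhere (movement-ecology convention, as in
  `geosphere::distGeo`); the printed site geometry (8.1 km / 65°, 7.3 km)
  reproduces only under the ellipsoid — a spherical mean-radius earth gives
  8.05 km, which rounds the wrong way.
* Vincenty convergence tolerance 1e-12 rad (≈ 6 µm); nearly antipodal
  non-convergence (unreachable here) falls back to the spherical formula.
* Duplicate timestamps are corruption, not ties: rejected, never averaged.
* Tracks are validated on construction (monotone time, ≥ 2 fixes, coordinate
  bounds); every malformed input maps to a named exception.
* REML non-convergence is flagged on the fit, not raised; singular/boundary
  V is reported with the offending component at zero.
* CSV outputs are written with fixed float formatting, so identical configs
  produce byte-identical report bundles.
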