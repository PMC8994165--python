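# Methods

This note documents the models behind the package, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical and design choices that were genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates, grids and the blind spot

All coordinates are degrees of visual angle in right-eye format:
positive x temporal, positive y superior.  Left-eye (OS) data are
mirrored (x ↦ −x) at import so one normative model serves both eyes;
for x-asymmetric grids such as the 24-2 (whose nasal extension column at
x = −27 has no temporal partner), the mirrored field lives on an
auto-registered mirrored grid rather than being force-matched.

The built-in 24-2 grid has 54 locations on a 6°-spaced lattice offset by
3° from the meridians, rows at y = ±3 extended nasally to x = −27.  The
two locations at (15, ±3) fall on the physiological blind spot and are
excluded from every statistic, leaving 52 analyzed locations.  Custom
grids come from cartesian, polar or explicit specifications; locations
must be unique and within ±90°.

## Voronoi tessellation

Tiles are built by intersecting half-planes against a convex clip
boundary (the convex hull of the locations dilated by half the median
nearest-neighbor distance, with mitre joins so the result stays a convex
polygon).  This O(n²) construction was chosen over clipping the
unbounded regions of a sweep-line Voronoi diagram because it is exact,
trivially bounded, and robust to collinear inputs; perimetric grids have
tens to a few hundred locations, where n² is negligible.  Two tiles are
adjacent when they share a boundary segment longer than 1e-9 degrees
(point contact does not count).  Construction-time invariants: each
generator lies inside its own tile and tile areas sum to the boundary
area within 1e-6 relative tolerance.

## Simulated observer

Responses are Bernoulli draws from the frequency-of-seeing curve
`fp + (1 − fp − fn) Φ((t − x)/σ)`.  The cumulative-Gaussian form in dB
is the standard simulation choice in perimetry; σ may optionally depend
on the threshold via a user-supplied function (variability grows in
damaged regions of real fields), but the default is constant.  Response
times are Gaussian (mean 400 ms, sd 60 ms) truncated to the response
window; they are reported but not analyzed.  Stimulus levels outside the
dynamic range are clamped, not rejected, because adaptive procedures
legitimately drive levels to the range limits; the response carries a
`clamped` flag.  The machine owns a single RNG seeded at open, so a full
session is bit-reproducible independent of procedure internals.

## Threshold procedures

**ZEST** defaults: domain 0–40 dB in 1 dB steps; bimodal prior with
weight 0.3 on a Gaussian kernel (sd 5 dB) at 0 dB and 0.7 on a kernel
(sd 5 dB) at the expected normal level; likelihood = the FoS curve with
spread 1.5 dB and false-response rates 0.03 baked in (these also guard
against a numerically vanishing posterior under contradictory
responses); stop when the posterior sd falls below 1.5 dB, with at least
4 and at most 25 presentations.  Next level and final estimate are the
posterior mean (the ZEST convention); the mode is available behind a
flag for QUEST-style behavior.  A fixed-count stopping rule is obtained
by setting `stop_sd=0`.  These values follow common perimetric ZEST
practice; all are configurable.

**4-2 staircase.**  Steps are 4 dB before the first response reversal
and 2 dB afterwards, where "afterwards" begins one move after the
reversal: the move made in direct response to the reversal still uses
the pre-reversal step.  (Concretely, from 25 with responses seen, seen,
not, not, seen the presented levels are 25, 29, 33, 29, 27.)  The second
reversal terminates the run with the midpoint of the last-seen and
last-not-seen levels.  If the next level would repeat a dynamic-range
bound, the run terminates pinned at that bound with the bound as
estimate.  **Full Threshold** runs one staircase and retests from the
first estimate when it lands ≥ 4 dB from the start, returning the second
estimate.

**MOCS** presents each level `reps` times in a seeded shuffled order and
fits (t, σ) by maximizing the Bernoulli likelihood of the FoS curve
(L-BFGS-B, σ bounded to [0.1, 20] dB).  Perfectly separated records and
failed optimizations fall back to linear interpolation of the 50%
crossing, flagged on the result; records that are all-seen or all-unseen
are an error (the level range cannot bracket the threshold).

## Whole-field orchestration

Growth waves are a breadth-first labeling over the Voronoi adjacency
from seed locations (24-2 default: the four primary points (±9, ±9)),
which makes every non-seed location's wave 1 + the minimum wave among
its neighbors and works identically on irregular grids.  A location
opens when at least one adjacent lower-wave location finishes (the
"all neighbors" variant would lengthen tests without a clear accuracy
gain at the noise levels simulated here); its ZEST prior peak (or
staircase start) is the inverse-distance-weighted mean of finished
neighbors' estimates, falling back to the dynamic-range midpoint.  Each
trial picks uniformly at random among open unfinished locations from a
scheduler RNG seeded separately from the machine RNG, so schedule and
responses reproduce independently.  Blind-spot locations are never
presented; they are treated as finished from the start so they do not
block the wavefront.  Catch trials are not inserted; the field's
false-response-rate entries are copied from the simulated observer's
configured rates.

## Normative models and deviations

Per location, ordinary least squares of sensitivity on age gives the
age-expected normal (intercept, slope) and residual sd.  Total-deviation
cutoffs at {0.5, 1, 2, 5}% are empirical quantiles (linear-interpolation
convention) of the cohort's TD residuals — no Gaussian assumption.
Pattern-deviation cutoffs are fitted the same way after subtracting each
cohort field's general height (85th percentile of its TD, the usual
convention for separating diffuse from focal loss; both the percentile
and the {0.5, 1, 2, 5}% display levels are configurable).  Probability
categories use strict inequality: a value exactly at the 5% cutoff is
"normal".  The `smooth` method shrinks each location's residual sd and
cutoffs toward its Voronoi neighbors (self weight 0.5, neighbors sharing
0.5) — a re-interpretation of classic dispersion-smoothing normative
techniques in terms that extend to irregular grids.  MD weights default
to normalized inverse residual variance (uniform available by flag);
zero-variance degenerate cohorts fall back to uniform weights.

## Progression

Pointwise linear regression uses time in years from the first visit
(dates must strictly increase; at least 4 visits).  The one-sided
p-value is the lower tail of t(m − 2) for the slope, per the alternative
"the location is deteriorating".  The residual MAD is the raw (unscaled)
median absolute deviation of the residuals; series with MAD > 2 dB are
flagged as highly variable.  PoPLR combines the per-location p-values as
S = Σ −ln max(pᵢ, 1e-6) — the floor keeps S finite on perfect trends —
and permutes the visit order jointly across locations (one shared
permutation per draw, preserving spatial correlation), 5000 draws by
default, sampled with replacement; the add-one p-value rule makes the
test super-uniform under the null by construction.  Requests exceeding
the size of the permutation group are capped with a warning.

A calibration subtlety: a series whose *raw sensitivities* are stable
acquires a small positive TD drift (+0.06 dB/year under the default
generator) because the age-expected normal declines while the series
does not, which makes the one-sided TD-based test conservative.  The
type-I error experiment therefore runs on raw sensitivities, where visit
exchangeability is exact; TD remains the default for clinical analysis.

## Synthetic data

Healthy cohorts follow a hill of vision: sensitivity
`h0 − k·ecc − γ·(age − 45) + subject offset + noise`, defaults h0 = 33
dB at fixation, k = 0.25 dB/degree, γ = 0.06 dB/year, between-subject sd
1 dB, test-retest sd 1.5 dB (optionally growing with eccentricity), ages
uniform on 20–80 years, 200 subjects.  These are plausible round numbers
for white-on-white perimetry in healthy adults, chosen once as the
package's study conditions.  Values are clamped to the dynamic range
after noise (a device reports nothing outside its range) and quantized
to 2 decimals to match the CSV representation.  Longitudinal series add
per-location linear slopes, a per-visit global fluctuation and
measurement noise to a baseline field.  All generators are pure
functions of (spec, seed).

What the generators do **not** emulate: learning and fatigue effects,
disease-specific scotoma shapes, threshold-dependent response
variability (unless configured), floor-effect censoring dynamics in
advanced damage, and spatially correlated measurement noise.  Passing
calibration and recovery tests therefore demonstrates internal
statistical correctness under the stated model, not performance on real
patient data.

## Problem sizes and numerics

The verification experiments use: the exhaustive ZEST posterior oracle
on a 9-level domain for all 126 response sequences up to length 6
(tolerance 1e-12; the sequential and one-shot products differ only by
rounding); 1000 single-location ZEST runs (thresholds 5–35 dB, σ = 1,
fp = fn = 0.03); all 64 length-6 staircase prefixes; 200 stable and 100
progressing series (10 visits over 5 years, 1 dB noise) with 500
permutations each; a 200-subject cohort with 500 held-out fields for
flag calibration; 1000 Voronoi probe points; and 100 whole-field
test-retest runs.  These sizes put Monte-Carlo error comfortably inside
the asserted bands while keeping the full suite in the tens of seconds.

Numerical choices worth knowing: ZEST snaps the posterior mean to the
nearest domain point (ties toward the lower level via argmin); the
regression core centers both time and values so a constant series yields
slope exactly 0 and p exactly 0.5, and zero-residual series map to
t = ±∞ → p ∈ {0, 1} rather than NaN; CSV sensitivities are serialized
with two decimals (missing = empty cell) making round trips bit-exact
for the values the package produces; dates are ISO 8601 and age is
stored as decimal years rather than derived from dates.

## Known limitations

Temporal (flicker) and kinetic stimuli are typed but not presentable by
the simulation backend; no catch-trial logic, fixation monitoring or
binocular scheduling; planar degree coordinates (no map projection for
very peripheral angles); normative fitting requires ≥ 20 subjects
spanning ≥ 20 years of age and a single grid.  The slope-recovery
coverage statistic is volatile across cohort seeds because the shared
between-subject offset correlates all locations' slope errors; its
acceptance check runs at a fixed seed, and `scripts/acceptance.py`
reports the per-seed value honestly.
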