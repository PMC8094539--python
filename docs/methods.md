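# Methods

## The analysis in one paragraph

Depth records from animal-borne TDRs are zero-offset corrected, segmented
into dives, and summarized per dive (duration, maximum depth, descent and
ascent times, bottom time, bottom vertical distance, post-dive surface
interval).  Dives are clustered into travel / explore / forage types by
k-means on (bottom time, duration, maximum depth), with the number of
types chosen by the Calinski–Harabasz criterion.  GPS fixes are
land-masked, speed-filtered, segmented into foraging trips, and
interpolated (monotone piecewise-cubic Hermite) to dive start times to
give each dive a position and a distance to the colony.  For foraging
dives, an Index of Patch Quality is computed by inverse optimality, bouts
are formed from the 325 s surface-gap rule, and a battery of eight linear
mixed models tests the IPQ's internal validity and the ecological
hypotheses (distance halo, seasonal change, breeding-stage effects).

## Optimal-diving model and the IPQ

Assumptions: (i) energy gain during the bottom phase is `g(t) = a·t^x`
with diminishing returns (0 < x < 1 in practice; values above 5 are
treated as unphysical and discarded); (ii) recovery at the surface after
a dive of duration `u` takes `s(u) = b·e^{c·u}`; (iii) divers maximize
the long-run rate `g(u−τ)/(u + s(u))`, where τ is the transit
(descent + ascent) time, measured per dive rather than approximated from
depth.  Setting the derivative in `u` to zero gives

x = (1 + bc·e^{cu})(u − τ) / (b·e^{cu} + u).

A common printed form of this identity has `bc·e^{cu} + u` in the
denominator.  That variant is *not* the first-order condition of the
stated rate; only the form above satisfies the round-trip test
(forward-simulate the optimal `u*` for a known x, then invert — the
package recovers x to 1e-7).  We therefore default to the consistent
form and keep the printed variant behind `form="as_printed"` for
comparability with older analyses.  Numerically the index is evaluated
via `exp(−cu)` so it cannot overflow for any dive duration.

`b` and `c` are shared constants estimated from all foraging dives with a
usable pause (0 < s ≤ 325 s), by Theil–Sen in log space: `c` is the
median of pairwise slopes of `log s` on `u`, and `log b` the median of
the implied intercepts.  This is the natural "median-based" estimator of
the two constants; ordinary least squares is available
(`method="ols"`).  Above 3,000 dives the input is thinned
deterministically (u-ordered, evenly spaced) because the pairwise-slope
matrix is O(n²).  Noiseless exponential data are recovered exactly;
under multiplicative lognormal noise (σ = 0.2, n = 2,000) both constants
come back within 5 %.

## Pipeline stages and their parameters

* **Zero-offset correction** — per 900 s window, the surface offset is
  the 0.05 depth quantile; the offset knot is anchored at the median time
  of the samples near that quantile (so a drifting baseline is tracked
  without lag) and offsets are interpolated linearly between knots, with
  linear extrapolation beyond the outer knots.  Windows whose quantile is
  not near-surface (> 10 m: fully submerged) are bridged.  A series
  shorter than one window falls back to a single global offset with a
  warning.
* **Dive detection** — maximal runs of samples ≥ 1 m lasting ≥ 5 s.
  These floors are configurable; they sit far below the travel-dive mode
  (~5.6 m, ~24 s) so the shallowest dive class remains detectable.
  Duration counts one sampling interval per submerged sample.  The
  post-dive surface interval is the gap to the next dive's start and is
  undefined for the last dive of a record (such dives are excluded from
  pause-model fitting and carry no IPQ).
* **Dive phases** — bottom phase is the span from the first to the last
  sample at ≥ 0.8 of maximum depth (a common biologging convention, the
  exact fraction configurable); descent/ascent are the transits to and
  from it; the three phases partition the dive to within one sampling
  interval.  Bottom vertical distance is Σ|Δdepth| within the bottom
  phase.
* **Impossible dives** — dives deeper than 200 m or longer than 360 s
  are removed as sensor malfunction (configurable caps; counts logged).
* **Speed filter** — a fix is excluded only when the great-circle speeds
  to *both* neighbours exceed 10 m/s; one pass, speeds recomputed once.
  An optional deterministic jump filter (off by default) removes single
  fixes displaced from both neighbours while the neighbours are close,
  standing in for manual inspection of tracks.
* **Trips** — maximal runs of ≥ 10 consecutive at-sea fixes spanning
  ≥ 1 h; trip duration runs between the bracketing land fixes when they
  exist.  Dive positions are interpolated with PCHIP on time (lat and lon
  independently, adequate far from the antimeridian/poles); dives falling
  in GPS gaps over 3,600 s are dropped from position-dependent analyses.
  Distances are haversine on a 6,371 km sphere (< 0.5 % from ellipsoidal
  at these scales).
* **Dive typing** — features are z-scored before k-means (otherwise
  duration dominates); centroids are reported in raw units; 25 restarts,
  seeded.  CH(k) = [B/(k−1)]/[W/(n−k)] over k = 2..8.  With k = 3,
  clusters map to travel/explore/forage by centroid depth (shallowest →
  travel); if duration or bottom-time orderings disagree, depth wins and
  a warning is emitted.
* **Bouts** — consecutive foraging dives with a surface gap < 325 s form
  a bout (n ≥ 2); runs of one are "single" dives.  Gaps are measured
  between consecutive *foraging* dives' end and start, regardless of any
  travel/explore dives in between.  The 325 s default can be re-estimated
  from data: a two-segment broken-stick regression (weighted by bin
  counts, since log-count variance scales as 1/count) on the
  log-frequency histogram of pauses returns the breakpoint.
* **Models** — all mixed models use a random intercept per bird, colony
  as a fixed effect, and maximum-likelihood (not REML) estimation so
  likelihood-ratio tests between nested fixed-effect structures are
  valid.  IPQ responses are square-root transformed exactly once, inside
  the fitting routine.  Significance of the predictor is the LRT against
  the same model without it; models 4–8 also test colony and are
  refitted per colony when it is significant (α = 0.05, no
  multiple-testing correction).  When every bird contributes at most one
  observation (or the mixed fit is singular) the random effect is
  dropped and a plain linear model used, flagged in the result; with one
  observation per bird the fallback reproduces OLS coefficients to 1e-8.
  The "near colony" radius is, per colony, the median maximum distance
  of trips shorter than 24 h (bracketing-fix duration).  Transition-stage
  birds (stage changed between deployment and retrieval) are excluded
  from the stage models (6–8).  Dates use a continuous seasonal axis:
  day-of-year, plus 365 in January/February.

## The synthetic generator

The generator is the package's test bed: it emulates a colony of
central-place foraging divers on a convex ~5 km island with two colonies,
and produces GPS fixes (4 min cadence), a 1 Hz depth trace, and truth
tables for every dive and trip.

* **Dive types.**  Travel / explore / forage dives mix in proportions
  0.40 / 0.39 / 0.21 with per-type mean structure (duration s, depth m,
  bottom s): travel (23.9, 5.6, 2.3), explore (69.8, 22.3, 9.3), forage
  (112.4, 61.6, 16.0).  Within-type SDs are generator choices (the field
  literature reports standard errors, not SDs): (4.5, 1.3, 0.8),
  (9.0, 4.5, 2.5), (13.0, 8.5, 4.0) — enough overlap to be non-trivial
  while keeping three resolvable clusters.
* **Patch-quality field.**  sqrt(x) = 0.32 + 0.0015·(distance, km) +
  0.0041·(day of season) + noise (patch-to-patch SD 0.06, dive-to-dive
  0.03, floored at 0.15).  The field is parameterized on the sqrt-IPQ
  scale because the hypothesis battery models sqrt-transformed IPQ — its
  fitted slopes are then directly comparable with the generator's
  parameters.
* **Forage dives are optimal.**  Given patch quality x and transit
  τ = 2(0.8·depth − 1.2 m)/(1.0 m/s), the dive duration is the
  rate-maximizing u* for the pause law (b = 20 s, c = 0.01 /s), found by
  bounded 1-D optimization of the log rate; the placed surface pause is
  b·e^{cu} times lognormal noise (σ = 0.10; σ = 0 gives the law
  exactly).  A vertical transit rate of 1.0 m/s makes the mean phase
  structure internally consistent with the population means above under
  the 0.8 bottom-fraction convention (τ ≈ 96 s at 61.6 m leaves ≈ 16 s
  of bottom time at u = 112.4 s).
* **Patches and bouts.**  A patch visit yields 1 + Poisson(24·x) dives,
  so poor patches naturally produce single (non-bout) dives, bout size
  grows with patch quality, and in-bout dives outscore singles — the
  qualitative signatures the validation models test.  Inter-patch
  surface intervals are 360–900 s (above the 325 s threshold);
  within-bout pauses are clipped below it.
* **Trips.**  Out-and-back at 2 m/s to a destination drawn at
  0.35–0.88 of the stage's maximum range (incubation 30 km, brood 12 km
  by default; transition birds travel like brooders), travel dives while
  commuting, patches and explore-dive runs at the destination with a
  small (< 1.5 km) meander.  The trip regenerates with a fresh draw if
  the destination leaves the 200 km bounding box.
* **Dive traces.**  Profiles enter at 1.2 m within the first sample (so
  a 1 m detection threshold recovers the full duration), transit to 80 %
  of max depth over τ/2 per side, and spend u − τ in the bottom phase; a
  wiggling segment of amplitude 4·x m encodes patch quality in the
  bottom vertical distance.  Max depth, duration and bottom time are
  reproduced within one sample.  Instrument artefacts: linear pressure
  drift (3 m per trip), 0.05 m depth noise, GPS dropout blocks
  (~0.8 %/fix), isolated 15–60 km outlier fixes (0.5 %), 25 m GPS noise.
* **Design for identifiability.**  Deployment dates for all breeding
  stages are drawn from a common window (season days 3–60).  Staggering
  them by stage — as real deployments are — would confound date with
  stage and distance and make the halo and seasonal slopes mutually
  unidentifiable at desk scale; the common window keeps each fitted
  slope an unbiased estimate of its generator parameter.  This, the
  linear sqrt-scale field, and the Poisson patch-size link are the main
  idealizations: real prey fields are patchy and advected, real bout
  structure is behaviourally richer, and real deployments are seasonally
  staggered.  Passing tests therefore demonstrate that the *pipeline*
  recovers known structure, not that real data meet these assumptions.

## Problem sizes used in the validation suite

Cluster selection and mean recovery use 30,000 sampled dives; IPQ
inversion uses 1,000 parameter tuples; pause-constant recovery uses
2,000 dives; LRT calibration uses 500 simulated datasets of 40 birds × 5
observations; slope-sign recovery uses 20 seeded seasons of 12 birds × 2
brood trips (truth tables, ipq + models stages); the end-to-end pipeline
tests use 6 birds × 2 trips with full 1 Hz traces.  These sizes were
chosen as the smallest giving stable recovery statistics.

## Known limitations

* Lat/lon are interpolated independently in degrees; do not use near the
  antimeridian or poles.
* The jump outlier filter targets single displaced fixes only; runs of
  two or more displaced fixes are kept (warned), as any automatic rule
  for longer runs risks deleting genuine excursions.
* Bout gaps are measured between consecutive foraging dives even when
  other dive types intervene; whether that matches any particular field
  protocol should be checked before comparing bout counts.
* The pause-threshold estimator assumes a decaying pause-frequency curve
  with a single slope change; multimodal pause distributions need a
  fixed threshold supplied by the analyst.
* Pooled (not per-colony) estimation of the pause constants b and c.
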