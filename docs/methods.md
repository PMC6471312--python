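# Methods

## Problem and data model

A sintered dental ceramic imaged by en-face (constant-depth) OCT shows
its granulation as backscatter texture.  When the oven temperature
deviates from the prescribed one, the granulation becomes inhomogeneous
and band-like bright/dark regions appear.  With the bands oriented
parallel to the y-axis, averaging the image rows gives a raw
reflectivity profile ρ(x) (gray levels vs lateral position in mm) whose
smoothed version — the averaged graph — has a characteristic low-order
shape per firing regime.  All quantities are computed on that graph and
on the raw profile's envelope.

Pixel convention: the abscissa of column j is (j + 0.5) · pitch with
pitch = lateral extent / width (default 3.25 mm / 500 px = 6.5 µm/px).
Depths quoted in air convert to in-material depths as z/n, with group
refractive index n ≈ 1.5 for dental ceramics at 1060 nm (so a 3.75 mm
axial range in air is 2.5 mm inside the material).

## Piecewise analytic models

The averaged graph is modeled by one to three quadratic segments, each
the unique parabola through a pass-through point with a prescribed
vertex: a = (ρ − ρ_v)/(x − x_v)², b = −2a·x_v, c = ρ_v + a·x_v².
Archetypes:

- **valley** — dip from (0, ρ0) to a shared vertex (x_m, ρ_min), then a
  rise to (x_max, ρ_max);
- **hump_valley** — a parabola from (0, ρ0) with local-maximum vertex
  (x_M, ρ_max), switching at x_i to a second parabola with vertex
  (x_m, ρ_min);
- **oscillation** — three congruent parabolas (|a| = 36A/x_max²) on
  thirds of the domain with vertices ρ0 − A, ρ0 + A, ρ0 − A; continuous
  and equal to ρ0 at the third-points;
- **ramp_plateau** — a parabola from (0, ρ0) with vertex (x_i, ρ_i),
  then constant ρ_i;
- **linear_ramp** and **flat**.

Intervals are half-open [lo, hi) with the last closed at x_max.  Built
models must be continuous at interior breakpoints to within 0.5 gray
levels (anchors read off printed graphs are rounded to about unit
precision).  Where published coefficient listings conflicted with their
own stated anchor points, the geometric construction (point + vertex)
was preferred, because it is self-consistent and reproduces the
independently tabulated gradient extremes.

## Fitting and archetype selection

`fit_model` minimizes the sum of squared residuals per archetype.
Breakpoints are searched exhaustively over the profile abscissae (the
shapes have at most one searched breakpoint; the oscillation thirds are
fixed by x_max), and for each candidate the segment coefficients solve a
linear least-squares problem — the procedure is deterministic, with no
random initialization.  The valley fit shares one vertex between both
segments (columns 1, (x−x_m)²·left, (x−x_m)²·right); the hump_valley
fit uses an unconstrained quadratic per side; ramp_plateau and
oscillation are linear in (ρ_i, a) and (ρ0, A) respectively.

`select_archetype` picks the archetype minimizing an AIC-equivalent
penalized SSE, `sse · exp(2p/n_eff)`, where p is the parameter count
(flat 1, linear 2, oscillation 2, ramp_plateau 3, valley 4,
hump_valley 7).  Because a moving average of window w leaves roughly
n/w statistically independent samples, a smoothed profile's n_eff is
n/w; without this correction the flexible shapes systematically win on
smoothed noise.  SSEs at numerical-noise level are floored to zero so
that exact fits tie and the tie-break selects the simpler shape.

## Parameters

From the fitted model: ρ_min/ρ_max are the analytic extremes (segment
vertices and interval endpoints), the gradient maximum is the largest
|2ax + b| over segment endpoints (the derivative is affine per
segment), the curvature maximum is max |2a|, and the mean level is the
exact segment integral divided by x_max.  From the raw profile:
(ρ_min)_peak/(ρ_max)_peak are the plain minimum and maximum — the
envelope including high-spatial-frequency granulation variation.  Taking
the graph extremes from the model (rather than the smoothed samples)
keeps the contrast and differential indicators referring to the same
object; an option to use smoothed-sample extremes is exposed.  Internal
computation is full precision; tables are rounded to two decimals.

## Verdict rules

- **normal** iff |k − 1| ≤ `normal_band`.
- Otherwise, direction evidence: a tilted linear graph (rising ramp)
  → over-fired, severe; mean level below `low_level_cut` × reference
  → under-fired; above `high_level_cut` × reference → over-fired;
  no or conflicting evidence → indeterminate.
- **severe** when |k − 1| > `severe_band` or the graph is tilted.

Defaults: normal_band 0.45 and severe_band 1.0 for pressed ceramics;
normal_band 0.15 for metal ceramics, whose correctly fired k is 1.00
and whose mildest deviations sit near 1.2 — the band is a per-material
calibration, not a physical constant, and every report embeds the
configuration used.  Level cuts default to 0.9/1.1 of the reference
level (the mean graph level of a correctly fired sample of the same
material, computed from the built-in anchors at call time).  Direction
cues are heuristics: a strongly over-fired pressed sample can also show
a depressed mean, in which case the class (deviated) is still right but
the direction may not be.

`rank_by_consistency` orders indicators by how monotonically they track
|temperature offset|.  Concordance is Kendall tau-a of indicator value
vs |offset|, computed separately on the under-fired branch (normal +
below-normal samples) and the over-fired branch, then averaged over
branches and cohorts.  The per-branch form expresses that a consistent
indicator grows as the temperature departs from normal in either
direction; pooling both branches would compare samples from different
physical regimes and dilutes the distinction.  On the two built-in
study cohorts this ranks k strictly above the contrast differences and
both differential indicators.

## Phantom generator

`render_enface` draws, deterministically for a given configuration:

1. a base field whose column means equal the archetype's ρ(x) at the
   column centers;
2. bright-spot texture: discs of radius 1–3 px and +120 gray levels,
   placed without overlap (≥ 2 px gap keeps them 8-disconnected, so a
   threshold-127 count recovers the planted number exactly).  The discs
   emulate resolved granulation clusters and the distinctive bright
   spots of over-fired samples — the leucite grains themselves (1–5 µm)
   are below the 10 µm lateral resolution.  The texture is
   double-centered (column- and row-mean-neutral): granulation
   redistributes backscatter locally rather than adding energy, so the
   averaged profile stays on the generating graph in both orientations;
3. noise: multiplicative unit-mean gamma speckle of scale 0.1 by
   default (OCT speckle is multiplicative; the distribution is
   configurable), or additive Gaussian;
4. 8-bit quantization (clip + round), applied last; ground truth stores
   the pre-quantization model, its parameter set and the planted grain
   count.

Default conditions mirror the study geometry: 3.25 mm square field,
500 × 500 px (tests use 128–256 px to keep runtimes short), grain
density 2 /mm².  The instrument's noise statistics are not published,
so the speckle scale is a free parameter, not a calibration.  What the
phantoms do **not** emulate: surface-curvature effects on the sampled
depth, depth-dependent attenuation, correlated speckle (real speckle
has a grain size set by the PSF; ours is i.i.d. per pixel), and layer
interfaces.  Passing recovery tests therefore demonstrates the
pipeline's correctness and noise robustness on band-structured images,
not instrument-grade validation.

## Numerical choices and edge cases

- Smoothing: centered moving average with a shrinking (truncated)
  window at the edges, so the domain is preserved; default window 5% of
  the profile length rounded to the nearest odd.  The published work
  does not state its smoothing method; this choice keeps the envelope
  oscillations in the raw profile but not the averaged graph.
- Binarization threshold is strict (> 127), matching the stated rule.
- Connectivity for bright-feature counting is 8-connected (the common
  blob-counting default; diagonal contact merges features).
- Orientation: rotate 90° iff the variance of row means exceeds that of
  column means; ties (flat images) are left unchanged.
- k is undefined for ρ_min = 0 (rejected); degenerate anchors collapse
  gracefully (a valley with ρ0 = ρ_min = ρ_max equals the flat model; a
  ramp with ρ0 = ρ_max is a constant line).
- Breakpoint recovery in the closed-form-vs-fit equivalence tests snaps
  generating breakpoints to the sampling grid, since the search is
  restricted to profile abscissae.

## Known limitations

- One representative profile per group; no inference across replicate
  samples (none are published).
- The verdict direction relies on a reference level of the same
  material; without it only the normal/deviated class is meaningful.
- Thresholds must be re-calibrated for new ceramic materials.
- No prediction of the actual oven temperature in °C — direction and
  severity only.
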