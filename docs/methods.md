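# Methods

## Boundary representation and conventions

A cell boundary is an ordered cyclic polygon of N vertices in µm
(default N = 400), with the implicit closing edge. Image pixel (row,
col) maps to (x, y) = (col, row) × pixel size, origin at the centre of
the top-left pixel. Orientation is always normalised so the shoelace
signed area is positive ("counterclockwise" in this mathematical
convention) before any downstream step: the tracking cost is
orientation-sensitive, and one convention stated once avoids a class of
sign bugs. Within a frame the N points are equidistant in arc length;
across frames the spacing changes with the perimeter, so every
index-to-µm conversion uses the per-frame spacing perimeter(t)/N.

Keeping N fixed (rather than fixed spacing) is what makes the rest of
the pipeline possible: the order-preserving bijections between two
cyclically ordered equal-count sets are exactly the N cyclic shifts, so
frame-to-frame correspondence becomes a one-dimensional minimisation,
and any per-point quantity becomes an N × T kymograph.

## Segmentation

Intensity frames are min-max normalised, Gaussian-smoothed (σ = 2 px)
and segmented with a parametric active contour
(`skimage.segmentation.active_contour`; elasticity α = 0.015, rigidity
β = 2, edge weight 1, step γ = 0.001, per-step move cap 0.2 px —
defaults tuned on the rendered simulator fixtures). The discrete snake
does not reach a fixed point on a step edge; it settles into a small
period-two breathing cycle (~0.3 px). Convergence is therefore declared
when the mean nearest-vertex distance between chunks of the same parity
(200 iterations apart) falls below 0.1 px, and the returned contour is
the average of the last two chunks, which cancels the breathing mode.
Failure to converge within 4000 iterations raises a segmentation error
carrying the frame index; scenes with zero or several above-threshold
objects raise an ambiguous-scene error. On a high-contrast disk the
result is within 0.8 px of the true edge everywhere.

Binary masks bypass the snake: the 0.5 level set of the filled,
single-object mask is traced by marching squares, and the staircase the
square lattice imposes is removed with a 5-point cyclic moving average
(~2 px of arc) before resampling — without it the staircase inflates
the perimeter of a rasterised circle by ~5%, which would leak into the
non-circularity measure. Frames where the object touches the image
border are flagged on the movie and refuse to enter tracking: every
downstream measure assumes a closed boundary.

Both routes end in the same resampling: arc-length-uniform placement of
N points starting from the first input vertex. Resampling an
already-uniform boundary is the identity to < 1e-6 µm.

## Tracking

`match_boundaries` scans all N cyclic shifts with exact arithmetic
(cost written as a running dot product; N = 400 makes O(N²) per frame
pair negligible) and breaks ties — which occur on symmetric shapes —
toward the smaller cyclically-signed |s|, then toward negative s, with
a 1e-9 relative tolerance so float round-off cannot make tie-breaking
platform-dependent. `track_series` matches each frame against the
already-aligned previous frame, so the recorded per-frame offset is
directly the cumulative shift to frame 0's numbering. No sub-point
interpolation is attempted: point identity is integral by construction.

## Curvature and whole-cell measures

Curvature at point i is the reciprocal circumradius of points
(i−h, i, i+h), cyclic, h = 10 by default; the sign is positive when the
midpoint of the flanking pair lies inside the boundary polygon
(point-in-polygon winding test), and collinear stencils give exactly 0.
Note the sign rule is orientation-independent, which is why the
orientation normalisation, not the sign rule, guards against reversed
input. The secant-circle estimator is biased low where the curvature
varies on the scale of the stencil: on a 10 × 5 µm ellipse at N = 400
the vertex curvature (true a/b² = 0.4 µm⁻¹) reads 4% low at h = 10 and
1% low at h = 5. For the cell-scale features the pipeline targets
(curvature radii ≳ 2 µm at ~0.13 µm spacing) the h = 10 bias is below
the other noise sources; quantitative point estimates of sharp features
should use a smaller stencil.

Kymograph smoothing is a separable moving average: cyclic over the
point axis, truncated-and-renormalised over time (no padding data is
invented at the movie ends). The 3 × 3 smoothed kymograph is the
*display* product; analysis (wave detection) runs on the raw one — the
3-frame box on a traveling, amplitude-modulated ridge drags the crest
toward the growth phase and was measured to bias recovered wave speeds
by ~−13%, while the raw crest follows the true bump path to ±2 indices.

Non-circularity is P/(2√(πA)) (shoelace area): 1 for a circle (the
400-gon discretisation error is +1.0e-5), larger for elongated shapes.
Centroid speed is the per-frame polygon-centroid displacement in
µm/min, undefined (NaN) at the first frame.

## Local motion

For each frame t, every point of boundary t is mapped to the nearest
point of boundary t + lag (lag fixed at 12 s of *time*, so a 4-s movie
uses 3 frames and a 2-s movie 6 — motion should dominate pixel noise at
equal physical lag regardless of acquisition rate). The raw
nearest-point map piles targets onto the closest flank of any
protrusion; smoothing the *target indices* (shortest-cyclic relative
shift, box-filtered cyclically with 19- then 15-point windows, then
arc-interpolated back to positions) redistributes the mapping across
protrusions and retractions. Index smoothing is the default because it
preserves the mapping's identity structure (vectors still end on the
later boundary); a `smoothing_domain="vector"` switch smooths the
displacement vectors instead, as a sensitivity check — on the uniform
inflation and simulator scenes the two variants agree in sign
everywhere and differ in magnitude well inside the closure tolerances. The motion value is the distance
from a point to its smoothed target, signed positive when the target
lies outside the earlier boundary polygon, with a normal-projection
override when the displacement is essentially normal and the
containment verdict disagrees (targets sitting numerically on the
boundary). A static movie gives exactly 0; a uniformly inflating
(deflating) circle gives +d (−d) everywhere.

Noise floor: with per-vertex jitter of σ, the smoothing removes most of
the target-side noise but the source point's own displacement survives,
so the floor is ~1.25σ (mean modulus of a 2-D normal), measured 1.6σ
with tangential leakage. The calibrated threshold used by the event
stage — 3 × RMS motion of a static calibration movie — sits safely
above this floor.

## Wave detection and speeds

The front and back of a polarised cell appear in the curvature
kymograph as two persistent high-curvature bands; waves are transient
tilted ridges between them. The band centres are the two largest maxima
of the *time-median* curvature profile separated by ≥ N/4 (the median,
not the mean: transient wave traffic occupies any given index a
minority of the time but biases the mean profile toward the birth zone
— measured 23 indices on the default simulation, enough to swallow
track births on one side). Indices within ±15 of either band are
excluded. Per frame, strict cyclic local maxima above an amplitude
floor (default: median + 2 scaled MADs of the band-excluded kymograph)
are linked greedily to the nearest active track, gated at `max_jump`
indices per frame; the gate should be sized to the fastest expected
wave, ceil(v_max·Δt/spacing) — the default 10 corresponds to ~19 µm/min
at the default simulated cell size. Tracks shorter than 5 frames are
dropped, as are tracks with |index slope| < 0.5 indices/frame:
persistent stationary ripples (e.g. pixelation of a static mask) are
not waves.

Speed relative to the cell is the Theil–Sen slope of the (cyclically
unwrapped) index trajectory × the time-mean point spacing of the
spanned frames × 60/Δt; speed relative to the substrate is the
Theil–Sen fit of the ridge's lab-frame (x, y) positions against time.
Theil–Sen is used because early track samples (growth phase, band-edge
emergence) are systematically displaced and a median-of-slopes fit
ignores them without explicit trimming. On simulator movies the median
recovered speed is within ~4% of the programmed 10–36 µm/min.

## Events, mean protrusion location, boundary MSD

Discrete protrusions (retractions) are strict local maxima (minima) of
the motion field over a ±7-index × ±1-frame neighbourhood, cyclic in
space, exceeding the noise threshold. Strictness matters: a steadily
advancing front is constant along the time axis and therefore never
produces an event, so the event count measures *initiations*, not
sustained motion. The neighbourhood halfwidth must also span the
per-frame crest travel of a traveling protrusion (v·Δt/spacing indices)
or one pseudopod will register several events; at the default window
this holds for waves up to ~13 µm/min, and the window should be widened
proportionally for faster ones. Rates are counts per observed minute;
across several movies the mean and SEM over movies are reported.

The mean protrusion location is the weight-w circular mean of boundary
index with w = max(motion, 0) (retractions: max(−motion, 0)), computed
by vector averaging of index angles. A frame is undefined when the peak
motion is below the noise threshold or the normalised resultant length
is < 0.1 (antipodal activity has no meaningful mean).

The boundary MSD accumulates shortest-cyclic index steps between
consecutive defined frames (converted with per-frame spacing) along
contiguous defined runs; gaps break accumulation rather than bridging
it. MSD(τ) averages over all intra-run pairs up to half the longest
run. Regime analysis: log-log slopes over 4–16 s (ballistic reference
2) and ≥ 60 s (caged reference 0), the crossover as the first lag where
the centred local slope drops below 1, and a conservative wave-speed
bound √MSD(τ₀)/τ₀ at τ₀ = 8 s — conservative because motion is measured
over a 12-s lag and the short-lag displacement is not perfectly
ballistic, so the bound sits below the true speed (verified against the
programmed simulator speed).

## The synthetic cell

The generator is a phenomenological shape model, not a mechanical one:
a radial contour r(θ) = R(1 + e·cos 2θ) around a translating centroid
(R = 8 µm, e = 0.15 → ~16 µm long axis, high-curvature front and back),
plus Gaussian arc-length bumps (σ = 1.5 µm, amplitude 1.5 µm — i.e.
pseudopod-scale, FWHM ≈ 3.5 µm) born `birth_offset` = 0.5 µm off the
front apex, advected rearward at the programmed arc speed along a side,
with amplitude (1 − e^(−age/10 s))·e^(−age/30 s) (rapid growth at the
front, slow decay while traveling — bumps fade before or upon reaching
the back band, where they are absorbed). Sides alternate with
probability `alternation_prob`; births are quasi-regular (intervals
60/rate s with 30% uniform jitter) rather than Poisson, because
pseudopod initiation is quasi-periodic and because at 10-minute movie
length a Poisson schedule would make any rate-recovery test measure
shot noise (±22% SD at 2/min) instead of the pipeline. An optional
round phase before `polarized_at` has e = 0, no translation, and small
short-lived non-traveling bumps; elongation, translation and traveling
waves ramp in over 60 s after the switch.

The radial construction cannot self-intersect but also cannot represent
overhangs, so bump amplitudes approaching the body radius raise an
error naming the offending parameters rather than producing a shape
outside the model's validity.

Rendering rasterises the filled polygon at 0.2 µm/px; the
pseudo-fluorescence channel is the blurred mask with Poisson shot noise
(200 expected counts in-cell), all drawn from the one seeded generator.
The log records every bump's birth time, side and exact per-frame arc
position, and `match_tracks_to_bumps` associates detected ridges with
logged bumps by path overlap for closure tests.

What the simulator does **not** emulate: pseudopod splitting and
merging, perimeter-conserving or area-conserving mechanics, motion blur
and uneven illumination, neighbouring cells, and any actin/myosin
mechanism. Passing the closure tests therefore shows the *measurement*
chain is faithful on clean, star-shaped, single-cell scenes; it does
not validate segmentation robustness on hard microscopy data.

## Problem sizes and numerical choices

Closure tests and the simulator defaults use 150-frame movies at 4-s
intervals and N = 400 — a scale where each full pipeline run takes a
few seconds and wave statistics (10–30 bumps per movie) are meaningful.
Key tolerances: resampling idempotence 1e-6 µm; tracking tie tolerance
1e-9 relative; curvature of collinear stencils exactly 0; circular-mean
degeneracy floor 0.1 resultant fraction; CSV round-trips use
`float_precision="round_trip"` so a boundary table re-read and re-run
reproduces downstream outputs byte for byte.
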