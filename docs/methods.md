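# Methods

`polarity-scope` quantifies light-directed cell polarization in budding
yeast time-lapse movies. This note records the models and procedures the
package implements, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where
the underlying experimental procedure left the design open.

## The polarization-efficiency statistic

For each cell, θ is the angle between the site of bud emergence and the
illumination target, measured at the mother-cell centroid, on [0, π].
The per-cell score is

    PE = 1 − 2θ/π

so a bud at the centre of the laser target scores 1, a bud diametrically
opposite scores −1, and an orthogonal bud scores 0. The population value
is the arithmetic mean with its standard error. Because the map is
linear, the population PE equals `1 − mean(θ)/90°` exactly; this is used
as an internal consistency check.

θ is measured between two directions from the mother centroid: toward
the bud centroid (taken a few frames after detection, when the bud
centroid is stable) and toward the active target position. The centroid
construction is the most literal reading of "angle between the site of
bud emergence and the laser position"; an arc-length variant can be
derived from the kymograph if needed, but the centroid form is
canonical here.

Scoring thresholds are strict exactly as printed: a bud is *on target*
iff θ < 45°; a *large bud* has area strictly greater than 4.5 µm²; a
cell is *polarized* iff a cortical accumulation persists strictly longer
than 15 min (a run of L consecutive positive frames spans
(L − 1)·Δt; gaps reset the run). Boundary cases (45°, 4.5 µm², exactly
15 min) therefore fall on the negative side, and the tests pin them.

## Membrane kymographs

Each frame's cell outline is resampled to 100 arc-length-uniform
positions. At each position the image is averaged over `band_width = 6`
bilinear samples taken at 1-px steps along the inward normal, starting
on the contour (membrane signal lies at or just inside the contour on
the synthetic data; the band direction is a fixed convention). Rows
stacked over time form the kymograph. Missing data — failed outlines,
bands leaving the field — is NaN, never zero.

The start point of the arc is not defined by the geometry alone, so the
origin is propagated frame to frame: each row anchors at the boundary
point nearest the previous row's origin. When a bud is detected, the
matrix is globally re-registered by a circular shift so the bud site
sits at arc 0, and the time axis is offset so bud emergence is t = 0 —
the convention in which these kymographs are displayed. A consequence of
the *global* shift is that in late post-emergence frames the bud-site
stripe drifts by a few samples as bud growth adds perimeter; the
registration is exact at emergence, which is where the annotations are
read.

On circles the linearization agrees with direct polar sampling of the
same inward band to < 3% of the dynamic range, and rotating image and
polygon together shifts the profile circularly by the matching number of
samples; both are regression-tested.

## Event detection

Manual by-eye appearance scoring is replaced by an explicit detector:
the windowed membrane trace (wrap-aware arc window, half-width 5
samples) must exceed the background mean by k = 3 standard deviations
for m = 3 consecutive frames; the appearance time is the first frame of
that run. Background statistics come from pre-illumination frames when a
pulse schedule is available, else from the first five rows. k and m are
configuration parameters; the defaults recover scripted onsets spanning
−40 to −5 min with a median error below one frame at the synthetic
noise level.

Whi5 nuclear exit is the first frame at which the mean intensity of the
nucleus (the brightest interior disc, radius 5 px by default) is no more
than 1.05× the mean of the remaining cytoplasm. The 5% tolerance is
needed because the brightest-disc estimator sits slightly above the
cytoplasmic mean even when Whi5 is fully cytoplasmic; without it, exit
would never be called on a constitutively cytoplasmic cell.

Competition between an old and a new target site is scored per move:
*Outcompeted* iff the old-site signal falls below detection for ≥ m
consecutive frames within the hold window **and** the new site's signal
appears within it; *Not Outcompeted* iff the old site persists
throughout and the new site never appears. Outcomes satisfying neither
clause (e.g. the old site fades but the new site never fills) are an
explicit *Indeterminate* category rather than being forced into the
binary; moves held for fewer than two frames are excluded.

Population kinetics are reported as the cumulative fraction of cells
whose signal has appeared, binned in half-open intervals labelled at
midpoints (midpoints at multiples of the bin width); the
half-population time is the first bin midpoint at which the fraction
reaches one half. Cells that never show signal stay in the denominator.

## Puncta colocalization

Cortical puncta are detected by Laplacian-of-Gaussian blob detection
restricted to a band within 4 px of the cell outline, with an intensity
gate of 3 robust standard deviations (median/MAD) above the on-membrane
background. Background is estimated on the membrane ring itself: mixing
in off-ring pixels deflates the threshold and produces false positives.

Colocalization between two channels is greedy nearest-first one-to-one
matching under a distance criterion (default 2 px ≈ 0.3 µm at
0.162 µm/px — a convention, reported with the output, since manual
counting has no explicit criterion). Ties are broken deterministically
by (distance, summed intensity, index). Both reciprocal fractions
(A-with-B, B-with-A) are reported; matched counts on the two sides are
equal by construction. Frame-to-frame turnover partitions the union of
two detections into same / appeared / disappeared. Pixel-correlation
measures are deliberately absent: the readout is a punctum count.

Fraction recovery is validated on scripted cells across overlap
fractions {0, 0.25, 0.5, 0.75, 1} with 20 puncta per channel. Twenty
puncta with a 2 px criterion need more perimeter than a 2.5 µm mother
provides (the generator refuses geometrically ambiguous layouts), so
these tests use a 7 µm cell — a realistic large mother, chosen once.

## Recruitment kinetics and the synthetic-movie generator

The optogenetic pair is modelled phenomenologically: each illumination
pulse contributes a unit-peak kernel that rises linearly over
`on_time = 10 s` (the measured relocation is faster than 10 s; only the
bound is stated, so the simplest rise meeting it is used) and then
decays exponentially from the peak with `dark_half_time = 80 s`. Pulses
superpose linearly, so the trace is in units of the single-pulse
plateau and a sustained train converges to the geometric-sum plateau
`1/(1 − 2^(−P/80))` for period P; frequent pulsing (3/min) therefore
sustains a higher plateau than 1/min, as it should. Fitting a single
exponential to the noise-free post-pulse trace returns the configured
half-time to machine precision; the 2% acceptance tolerance absorbs
discretization of coarser sampling.

The generator renders, per frame and channel, on a
100 px (16.2 µm) field at 0.162 µm/px:

- **Geometry.** Mothers are circles; buds are tangent circles growing
  linearly in radius (2 × 10⁻³ µm/s default) from the scripted
  emergence time. Coordinates are pixel-centred, origin top-left, x
  rightward, y downward, angles counter-clockwise from +x; the same
  convention is stated in the ground-truth sidecar.
- **Membrane.** A Gaussian-profile annulus (σ = 0.25 µm) at the cell
  radius; radial intensity maxima thus lie on the true outline (tested
  to 1 px).
- **Fluorescence channels.** A base membrane level, plus recruitment at
  the active target (amplitude = peak level × kinetics trace, spread as
  an angular Gaussian with σ = footprint/radius), plus scripted
  accumulation at the future bud site from the channel's onset event
  (offsets relative to bud emergence, defaults −25 min Whi5 exit,
  −13 min Bem1, −12 min biosensor, −27 min biosensor under recruitment),
  plus scripted cortical puncta.
- **Whi5 channel.** A nuclear disc whose excess over the cytoplasm
  decays linearly to zero over the 3 min before the scripted exit.
- **Noise.** `counts = offset + gain·Poisson(signal/gain) + N(0, read)`,
  so a flat region of mean photon signal m has variance
  `gain·m + read²` (tested). All randomness flows from one seeded
  generator; identical configuration and seed give bit-identical movies.

What the generator does **not** emulate: irregular cell shapes, focus
drift, photobleaching, cell motility, crowded/touching cells, uneven
illumination, and any actual Cdc42 biochemistry — fluorescence follows
the script, not a reaction–diffusion model, and the reference channel
is a plain cell-body mask, not phase-contrast optics. Passing tests
therefore demonstrate that the measurement chain recovers known inputs
under controlled imaging conditions; they do not certify segmentation
robustness on real micrographs, where an active-contour tracker would
replace the threshold segmenter behind the same interface.

Known generator-analysis interaction: bud emergence is detected 1–5
frames after the scripted time, because a merged mother+bud outline is
split by subtracting the mother's (dilated) first-frame footprint and
the residual must first clear a minimum area. θ is unaffected (centroid
directions), and appearance times are on the movie clock.

## Bud-site bias Monte Carlo

Responders polarize with a prescribed PE (default 0.75 ⇒ θ = 22.5°,
noiseless by default, optional Gaussian angular jitter truncated to
[0°, 180°]). Non-responders draw θ from a distribution on 46°–180°
with mean 90° (model 1, the fully random expectation) or 102° (model 2,
the measured aggregate bias). Only the range and mean are prescribed;
a uniform on 46°–180° has mean 113°, so a shape must be chosen. The
package uses the simplest family meeting both constraints: a linear
tilt on the range, clipped at zero and renormalized where necessary.
An everywhere-positive straight line can only shift the mean by
(width)/6 ≈ 22.3°, which stops just short of 90°; allowing the line to
reach zero inside the range (continuously deforming toward a triangle
pressed against the lower end) covers every mean strictly inside the
interval. The realized density is exposed on the distribution object so
its shape is never hidden. Sampling is inverse-CDF on a 4096-point
grid (discretization bias ≪ 0.05°).

The fully random null draws target and bud independently and uniformly
on the circle; the minimal angular difference is then itself uniform on
[0°, 180°], hence the analytic mean of 90° that the Monte Carlo
reproduces to ±0.3° at 10⁵ draws.

## Numerical choices and degenerate inputs

- Polygon orientation is normalized to positive signed area; areas and
  centroids use the shoelace formulas and are invariant to vertex
  rotation.
- Sub-pixel sampling is bilinear everywhere (order-1
  `map_coordinates`).
- `map_point_to_arc` refuses near-equidistant queries (spread of
  boundary distances < 0.5 px), e.g. the centre of a circle.
- Tracking ties (two candidates within 1 px of each other inside the
  displacement gate) are broken by the smaller area change and logged.
- Empty segmentations, blank cells and cells leaving the field yield
  empty results or truncated, flagged tracks — not errors.
- The 180° relative-intensity control window shifts to the nearest
  clear arc position (and says so) when it would overlap the bud or a
  second target.

## Problem sizes used in the test suite

Recovery tests run at deliberately small scale chosen to exercise every
code path with tight statistics: 50 single-cell movies (58 frames,
100×100 px) for population-PE recovery; 8 movies (97 frames) for
appearance-time recovery; five single-frame scenes of 20+20 puncta for
colocalization recovery; 20 synthesized kymographs for competition
scoring; 10⁵ draws for the Monte Carlo checks.
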