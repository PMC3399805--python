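# Methods

This note records how the estimators and generators in `vascomplex` are
defined, the defaults they use, and the design choices behind them.

## Binary inputs and preprocessing

All estimators consume 2-D `{0,1}` rasters, row-major, origin top-left;
foreground 1 marks vessel. The preprocessing chain for angiographic
volumes is: maximum-intensity projection along a chosen axis (axial by
default), two-cluster k-means segmentation of the projected intensities,
Zhang–Suen thinning to a 1-pixel skeleton, and a left/right split along
the image width. "Left hemisphere" always means the left half of the
image; mapping display orientation to anatomy is the caller's concern and
should be recorded in the caller's configuration.

The 1-D two-means step is solved exactly: the threshold over the sorted
unique intensities that minimizes the within-cluster sum of squares
(prefix-sum search). This removes initialization randomness, makes the
result invariant to positive affine intensity rescaling, and is
symmetric under contrast inversion. A constant image has no contrast and
is rejected.

## Box-counting dimension

Dyadic box sides ε = 1, 2, 4, … up to the larger image extent, grid
anchored at the top-left pixel, partial boxes at the right/bottom edges
counted. `D_b = −slope` of the OLS fit of log N(ε) on log ε over the
selected window. The anchor is configurable because the count of a
non-power-of-two image depends on where the grid sits — that dependence
is precisely the matrix-size sensitivity the simulation experiment
measures, so it must be fixed and reproducible, not averaged away.
The series is built bottom-up (ε = 1 upward); top-down halving from "one
box covering the image" is the same dyadic set but leaves the largest ε
ambiguous for non-square images.

## Minkowski (dilation) dimension

The image is dilated with square structuring elements of side 2n+1 for
n = 0…20 (default), radius r = (2n+1)/2, and the dilated foreground area
A(r) recorded; `D_m = 2 − slope` of log A vs log r. A single chessboard
distance transform yields all areas at once (a pixel is in the
n-dilation iff its Chebyshev distance to the foreground is ≤ n), which
is exact and O(HW). Dilations clip at the canvas, as they do in any
raster tool. The proportionality constant in r is irrelevant to the
slope (log-shift invariance); only range selection sees it. The n = 0
point (area = foreground count) is included with no special-casing.
n_max = 20 suits images a few hundred pixels across; for much smaller
objects the radii should be scaled down with the object, since beyond
its self-similar range a thin structure just looks one-dimensional.

## Scaling-range selection

Real rasters scale linearly only over a window, and the number of fitted
points drives the absolute FD value. The window is chosen by a
correlation threshold: the longest contiguous window whose log-log
Pearson |R| ≥ 0.995 (default), ties broken toward the smaller starting
scale. If no 3-point window qualifies, the best 3-point window is
returned flagged. A window with constant ordinate (e.g. N(ε) = 1 for a
single point) is treated as perfectly linear with slope 0, which makes
the degenerate cases (single pixel → dimension 0, saturated area →
dimension 2) come out right without special paths.

For cohort analyses the window is selected once per estimator on the
scale-wise mean of all log-log curves and reused for every image, so
each subject contributes the same number of points to each regression.
Per-image selection can hop between adjacent windows on near-identical
images, adding between-subject variance that has nothing to do with the
vasculature; a constant window removes it. The single-image API keeps
per-image selection.

## Generalized dimensions

Partition moments M(q, l) = Σᵢ (Mᵢ/M₀)^q are computed over the same
top-left-anchored dyadic box sizes, occupied boxes only, with the
Shannon sum Σ μᵢ log μᵢ at q = 1. The default q grid is 0 to 5 in steps
of 0.25; negative q is excluded because box masses of a sparse skeleton
make q < 0 moments blow up on near-empty boxes.

Two choices differ deliberately from the free-intercept OLS used for
`D_b`:

1. **Box-size window.** Only scales at which the average occupied box
   holds ≥ 4 pixels enter the fit (falling back to the three coarsest
   sizes). On a 1-pixel-wide skeleton the finest boxes hold exactly one
   pixel each, so the coarse-grained measure is pinned uniform there and
   carries no multifractal information.
2. **Anchored regression.** The scaling law is exact at the single-box
   scale — M(q, L) = 1 — so the regression is constrained through that
   point (through the origin in log(l/L) coordinates). Each D_q is then
   a positive-weighted average of the per-scale Rényi entropies
   H_q(l)/log(L/l), which are non-increasing in q for *any* measure:
   the dimension inequality D₀ ≥ D₁ ≥ D₂ holds for every input by
   construction. A free-intercept fit spanning the pinned fine scales
   can invert the ordering on skeleton images — the inversion is a
   finite-size artifact of the chord slopes, not a property of the
   measure.

Consequence: the capacity dimension D₀ from the anchored fit is a
different estimator from the free-intercept box-counting `D_b`, and the
two are not expected to agree numerically on natural images (they do
agree on exactly self-similar, grid-aligned sets). Both are reported
side by side in the cohort tables.

On the binomial multiplicative cascade (weight p, depth k), whose Rényi
spectrum is known in closed form, the anchored estimator reproduces
log₂(p^q + (1−p)^q)/(1−q) to machine precision from the exact measure
and to < 0.05 from an integer-rounded raster of it.

## DLA simulator

On-lattice diffusion-limited aggregation: walkers launched on a circle
at (cluster radius + 5) pixels take 4-neighbor lattice steps and freeze
on first 4-adjacency contact with the aggregate (8-neighbor sticking is
available). Walkers beyond 3× the launch radius are relaunched; walkers
far outside the launch circle jump inward by their slack distance in a
uniform random direction, which is exact for an unbiased walk and keeps
growth fast. Growth stops when the cluster radius reaches 0.45 of the
smaller half-extent of the grid (default), or on budget exhaustion; the
budget counts frozen particles including the seed. With the default
stopping rule a 512×512 cluster has a few thousand pixels and wide empty
margins — margins matter, because box counting is sensitive to them
while the dilation method is not, and that contrast is the point of the
simulation. The 364×436 geometry is produced by growing on 436×436 and
center-cropping the width, so identical morphology is measured on both
matrix sizes. Everything is deterministic per RNG seed.

## Synthetic AVM cohort

Each hemisphere is a recursive bifurcating tree rasterized 1 pixel wide
on a 436×182 canvas (trunk 85 px at the bottom center, two children per
node, length decay 0.74 with 12% jitter, branching angle 27° with 9°
jitter, 7 levels), then thinned. Patients receive d extra vessels on a
randomly assigned AVM side, d uniform on 10…160: 65% as short strokes
scattered in a disk whose radius grows like √d (constant tangle density,
so thinning never erases the added complexity) and 35% as feeding
vessels converging radially on the tangle from across the hemisphere.
Purely compact tangles concentrate the measure and depress D₁/D₂; the
feeder component spreads the added mass the way feeding arteries do, and
with it all five dimension estimates rise on the AVM side. Controls are
generated symmetrically.

The intensity-time curve is a gamma-variate bolus (onset 8 s, shape 3,
scale 1.8 s, sampled at 0.5 s for 60 s) whose amplitude is set so that
the peak upslope equals 0.5 + 0.02 × (total branch count) arbitrary
units/s, plus Gaussian noise (SD 0.05 by default). The four nidus
diameters are D(1±u) per view with u uniform on [0.1, 0.3] and
D = 0.8 + 0.02 d cm, so their mean is exactly D and monotone in d.
A `nidus_center_jitter` dial (default on) randomizes the tangle
location; setting it and the noise SDs to zero gives the low-noise
configuration used for parameter-recovery checks.

What the generator emulates: the paired left/right design; skeleton-like
binary inputs at the in-vivo matrix size; a strictly more complex
affected hemisphere; monotone complexity→flow and complexity→nidus-size
links with tunable noise; multifractal (strictly decreasing) spectra.
What it does not emulate: hemodynamics, anatomy (no circle of Willis, no
territory geometry), MR physics, projection artifacts, or segmentation
errors. Tests passing on this cohort show the pipeline recovers planted
relationships from skeleton images; they say nothing about segmentation
quality or scanner effects on real data.

## Statistics

The cohort report gives means ± SEM per group cell, paired t statistics
for AVM-vs-contralateral and left-vs-right contrasts, Pearson r with
two-sided p (t transform) and the OLS line for FD-vs-covariate
correlations, and the Fisher-z sample size
n = ⌈((z₁₋α/₂ + z_power)/atanh r)² + 3⌉ with α = 0.05 two-sided and
power 0.80, computed with exact normal quantiles. Omnibus ANOVA,
normality tests and multiplicity corrections are deliberately left to
standard statistical software; they are routine and orthogonal to the
estimators. p-values are reported unadjusted, one per correlation.

## Problem sizes and determinism

Default analysis sizes: 10 DLA replicates per geometry for the
simulation block, 10 patients + 10 controls for cohort runs — a few
seconds each on one CPU, with all randomness derived from a single seed
(per-subject and per-replicate streams are spawned from it, so reports
are byte-reproducible). The acceptance script uses exactly these sizes.

## Known limitations

- Absolute FD values depend on grid anchor, margins, and the regression
  window; only like-for-like comparisons (same pipeline, same window
  policy) are meaningful.
- The estimators are 2-D; projections of 3-D vasculature compress the
  true structure, and values between 1 and 2 reflect the projection.
- The box-counting whole-vs-half discrepancy on power-of-two grids is
  small but not exactly zero under the maximal-window rule, because the
  saturated coarsest scales stay in the fit when the curve is straight
  enough to pass the R threshold.
- Sampled nidus diameters and transit slopes are affine stand-ins, not
  physiology; their noise parameters are dials, not measurements.
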