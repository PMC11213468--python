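# Methods

## Coordinate and flow conventions

Images are 2D arrays indexed `(row, col)` = `(y, x)`, origin top-left,
pixel centers at integer coordinates. The flow direction is a unit vector
`(dx, dy)` in these coordinates, supplied as experimental metadata per
field of view — it is never inferred from cell morphology, because
upstream/downstream identity is an experimental fact and inferring it
would silently break the flow-reversal symmetry the pipeline guarantees.
The scalar projection of a pixel onto the flow axis is `p = x·dx + y·dy`;
larger `p` is further downstream.

## Cell geometry

**Segmentation.** Cells are recovered by seeded watershed using the
smoothed junction-marker image as the elevation map (bright cell-cell
ridges act as barriers). Seeds are one point per nucleus: local maxima of
the smoothed nucleus channel above its Otsu threshold, at least
`min_seed_distance` (default 10 px) apart — point seeds keep touching
nuclei from merging into a single basin. Without a nucleus channel, local
minima of the elevation map seed the watershed. Fragments below
`min_cell_area_px` (default 50) are dropped. Externally produced label
masks are accepted unchanged through a first-class input path, since many
labs outline cells by hand or with their own tools.

**Full-length filtering.** Any cell whose mask touches the outermost image
row or column is excluded: a partial cell has no meaningful upstream or
downstream end.

**Aspect ratio** is the major/minor axis ratio of the mask's
moment-equivalent ellipse (second central moments of the pixel
coordinates). The minor axis is floored at 1 px so skeletal masks return
a finite, large value.

**Tripartition.** "Equal-length segments" means equal extent of the scalar
projection onto the flow axis — not equal area, and not arc length along a
curved midline. The projected span `[p_min, p_max]` is cut into three
equal intervals; the decision rule is written symmetrically about the span
center (strict inequalities at ±span/6), so pixels landing exactly on a
cut go to the mid-body under either flow sign and **negating the flow
vector swaps the upstream and downstream masks exactly**, with the
mid-body invariant. Cells with projected span < 3 px cannot be
partitioned and are reported, not silently dropped. Discretization note:
the three cut intervals are exactly equal, while the measured pixel-center
spans of the segments can differ from each other by up to one pixel.

## Polarity

Per-segment intensity is the **mean** (not sum) of background-subtracted
pixel values over the segment mask, so segments of unequal pixel count
remain comparable. Background defaults to the median over background
(label-0) pixels of the *unfiltered* segmentation — after border-cell
filtering the dropped cells are relabeled 0 and would contaminate the
estimate — and can be overridden by a config scalar. Values driven
negative by subtraction are clipped at 0 and the clipped count logged.

The polarity index is `down / (up + mid + down)`: 1/3 for uniform
staining, 3/5 for a 3-fold downstream enrichment, 1 for complete
downstream confinement. It is invariant to multiplying the image by any
positive constant. A cell whose intensity sum is zero has an undefined
index and is flagged and excluded from group statistics rather than
imputed.

Laurdan generalized polarization is computed pixel-wise as
`GP = (I_ord − G·I_dis) / (I_ord + G·I_dis)` with the G factor defaulting
to 1 (no calibration standard assumed; configurable). Zero-denominator
pixels are NaN. GP is antisymmetric under channel swap at G = 1.

The statistical layer is deliberately thin: one-way ANOVA with Tukey HSD
across the three segments (scipy), or an unpaired two-tailed t test for
two groups. `anova_null_calibration` re-runs the identical F test over
vectorized null simulations to report its empirical type-I error.

## Cluster and puncta metrics

Detection: pixels outside the cell are filled with the within-cell median
(a raw intensity step at the cell boundary would ring through the top-hat
as a false ridge), then a white top-hat with a disk of radius 5 px removes
background and structures larger than the element. The threshold is Otsu
over the within-cell top-hat values, **floored at median + 6·MAD** of
those values: Otsu presumes a bimodal histogram and collapses into the
noise when a cell contains few or no puncta; the robust floor covers that
case. Smoothing (optional, off by default), top-hat, Otsu, median and MAD
are all equivariant under multiplication by a positive constant, so
detection is intensity-scale invariant. Components are 8-connected with
`min_area` 4 px²; each cluster is assigned whole to the segment containing
its centroid so counts stay integral, and per-segment counts always sum to
the per-cell total.

Because the field does not define "cluster index" uniquely, two summaries
are computed side by side: the **clustered-area fraction** of each segment
(default index, in [0, 1]) and the **mean cluster area** per segment (so
fold-changes in cluster *size* are measurable independently of cluster
*number*). A punctum, for PLA-style counting, is a detected cluster whose
area falls inside a configurable size band (default 4–200 px²).

## Calcium activity

Traces are per-frame means over each ROI (whole cell and the three
segments) minus the per-frame background median, in camera units. The
whole-cell trace is exactly the area-weighted mean of the segment traces.
The frame interval defaults to 3 s but is carried as metadata, never
assumed.

The activity statistic is the **index of dispersion**
`IoD = s²/x̄` with the sample (n−1) variance. A constant trace gives 0;
independent Poisson samples give ≈ 1; oscillations inflate it far beyond.
IoD is *not* scale-invariant (`IoD(c·x) = c·IoD(x)`), so traces are kept
in fixed background-subtracted camera units before thresholding, and the
threshold (default 2) is a config key. Optional detrending (linear or
exponential, for photobleaching) removes a fitted baseline and re-centers
the trace on its original mean so the IoD scale is preserved; a
non-convergent exponential fit falls back to linear with a warning.

A cell is **active** when the whole-cell trace *or any* segment trace
exceeds the threshold (the more sensitive of the two conventions; both
IoDs are always reported). Localization: no segment above threshold →
`inactive`; exactly one → that segment's name; several → `whole_cell`
(spatially unconfined). A cell active only through its whole-cell trace is
also `whole_cell`. The scheme generalizes the downstream/whole-cell
dichotomy usually displayed for flow-aligned cells.

Peaks are local maxima with prominence ≥ k·MAD of the trace (default
k = 5) separated by at least 9 s; when the MAD is zero but the trace is
not flat, any positive prominence counts, leaving only the separation
rule. Population summaries report the active fraction and per-category
shares among active cells; aspect-ratio-vs-activity association uses
Pearson's r with its two-sided p-value.

## Synthetic data generator

The generator renders the statistical structure the analysis assumes,
with exact ground truth, so every stage is testable closed-loop:

- **Mosaic**: seeds on a jittered grid in flow-rotated coordinates; each
  pixel joins the seed minimizing an anisotropic distance whose
  along-flow axis is shrunk by the seed's stretch factor (drawn from the
  aspect-ratio distribution, default 4.0 ± 0.8 — the elongation regime in
  which flow-aligned cells sustain localized signaling). This stretched
  Voronoi tessellation guarantees tiling and controllable elongation;
  1-to-2-px background ribbons are carved at label boundaries (they double
  as the junction ridge and the background for median estimation).
  Disconnected fragments are reassigned so every label is 4-connected.
- **Channels**: junction = blurred boundary ridges; nucleus = one Gaussian
  blob per cell; stain = per-segment constant levels `base·(1, 1, fold)`
  with fold defaulting to 3 (downstream enrichment); puncta = flat-top
  disks (radius 2 px) so the ground-truth spot area is analytic, placed at
  per-segment densities (default 6× downstream) with a minimum
  center-to-center separation (PLA puncta are discrete, resolvable
  objects).
- **Movies**: per-cell baseline 100, oscillation added only over the
  sampled source region of active cells (sine with random phase, or a
  transient train with recorded event times; amplitude 100, period 60 s),
  optional exponential photobleaching. Defaults emulate the population
  structure of a monolayer under high laminar shear: active fraction 0.5
  and downstream-restricted localization in 75% of active cells.
- **Noise**: signal-dependent Poisson with gain g (variance = g·mean on a
  uniform region; default 1) followed by additive Gaussian read noise
  (default SD 2), a standard two-stage approximation of sCMOS acquisition.
- **Determinism**: one integer seed drives every random draw; identical
  seeds reproduce bit-identical images, movies and ground truth.

What the generator does **not** emulate — and what passing closed-loop
tests therefore cannot show about real data: membrane texture and
intracellular structure, segmentation errors of real junction stains,
curved cell midlines (segments are defined by projection), spatially
varying illumination, focus drift, and any mechanochemistry linking shear
to transport. Absolute IoD values are unit-dependent and depend on
unstated acquisition conventions, so only the thresholding logic — not
numeric IoD values — transfers between datasets.

## Problem sizes

The defaults used by the tests and the acceptance script are desk-scale by
design: 200-cell scenes for partition checks, a 400-cell / 200-frame
movie (≈300 analyzable full-length cells) for activity-call recovery, a
600–1000-cell noise-only movie for specificity, 10,000 null simulations
for ANOVA calibration, and 1,000 Poisson traces of length 600 for IoD
calibration. These sizes put Monte-Carlo error comfortably inside the
stated tolerances while keeping a full run in minutes on one CPU.

## Known limitations

- Watershed accuracy is reported (mean Jaccard ≈ 0.9 on synthetic scenes)
  but boundary-ribbon pixels are assigned to cells, so masks are a pixel
  or two generous relative to ground truth.
- "Equal-length" by projection differs from arc length along a midline
  for strongly curved cells; for the near-convex elongated cells the
  tessellation produces, the two coincide closely.
- The cluster index definition (area fraction) is one of several in use;
  mean cluster area is reported alongside for comparability, and both are
  labeled in the outputs.
- Border-cell exclusion biases sampling toward the field center; the
  reported `n` is always the post-filter count.
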