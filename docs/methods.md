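# Methods

This note documents the models, conventions, and numerical choices behind
each stage of the pipeline, and what the synthetic validation does and does
not establish about real data.

## Units and image conventions

All physical lengths are nanometers internally; angstroms are accepted at
the boundaries (MRC headers, pixel-size overrides, lowpass cutoffs) and
converted once. Images use a top-left origin with x rightward (columns),
y downward (rows), and pixel centers at integer coordinates; contours are
`(x, y)` vertex lists in pixel units. Measurement tables are CSV with a
schema-version header line; every row carries the `source_id` of the image
it came from, and pipeline runs store a config hash, seed, and package
version in a JSON sidecar.

## Synthetic scenes

The generator renders the two EM contrast regimes the detector must handle:

* **cryo**: a projected spherical vesicle is a dark annulus — the bilayer
  rim — over a uniform background; the interior is at background level. The
  rim thickness defaults to 5 nm, a typical bilayer scale. Contrast depth is
  1.0 intensity unit below background, so a Gaussian noise sd of 0.2 gives a
  signal-to-noise ratio of 5.
* **nstem**: a vesicle is a uniformly dark body whose boundary radius is
  perturbed by a smooth seeded harmonic series (sd ≈ 1 px), emulating the
  rough, irregular edges of negatively stained, dehydrated vesicles.

Tubular vesicles are capsules — a rectangle with semicircular caps,
parameterized by width and tip-to-tip length — optionally bent along a
circular arc, which keeps a two-parameter analytic ground truth while
producing the long, bent shapes seen in heavily tubulated EV preparations.
The true roundness of each capsule is computed from the moments of its
anti-aliased rendered mask, so downstream classification can be scored
without a separate geometric derivation.

Shapes are anti-aliased by 4× supersampling of each shape's bounding patch
followed by box down-sampling, giving sub-pixel diameter accuracy. Noise is
additive Gaussian plus signal-dependent (shot-like) noise over a slowly
varying background (tilted plane plus one broad sinusoid). All randomness
flows from explicit integer seeds through separate child generators for
background, per-shape roughness, and pixel noise; identical specs render
bit-identical images.

The generator does **not** simulate electron optics: no contrast transfer
function, defocus, dose fractionation, stain granularity, or overlapping
projected density from three-dimensional structure. Passing the recovery
benchmarks therefore demonstrates correctness of the measurement chain
(segmentation geometry, unit handling, estimator definitions, statistical
conventions) under controlled contrast and noise — not segmentation
performance on arbitrary real micrographs, where thresholds and filters are
exposed as configuration for tuning.

### Standard benchmark scene

One 3072 × 3072 px cryo-style micrograph at 2 nm/px: 200 spheres with
diameters uniform in 40–250 nm and 20 capsules of width 42 nm and length
120–280 nm (every fourth bent, arc radius 150–400 nm), placed on a jittered
15 × 15 grid so no two shapes touch and none touches the border; Gaussian
noise sd 0.2 (SNR 5), shot scale 0.02, background amplitude 0.1. The
tubular fraction by construction is 20/220 = 9.09 %. Problem sizes
throughout (one 3072² scene; 24 montages of 768² per membrane condition;
50-bead montages) were chosen as the smallest at which the recovery
estimates are limited by the method rather than by sampling noise.

### Membrane-coverage scenes

Negative-stain-style montages with exactly known coverage: spheres
(60–200 nm) are dropped uniformly at random, overlaps allowed, onto an
occupancy grid; placement stops at the crossing of the target fraction that
lands closest to it, and the realized truth is the mean of the rendered
union coverage mask. The two-condition yield experiment draws per-montage
coverages from N(0.056, 0.005²) and N(0.010, 0.002²) — a 5.6-fold difference
in means.

## Vesicle detection

Chain: large-kernel median background flattening (estimated on an
8×-decimated grid) → polarity normalization (features dark in both
modalities) → isotropic Fourier lowpass with cosine rolloff (cryo only;
`None` means max(5 Å, 6 px), reproducing the conventional 5 Å display filter
at real cryo pixel sizes while staying above Nyquist for coarser synthetic
pixels) → threshold (Otsu default; a robust median ± k·MAD alternative is
selectable) → morphological closing and hole filling (a cryo rim ring
encloses a background-level lumen) → connected components → watershed
splitting → half-maximum contour refinement → sub-pixel marching-squares
contours.

Two details matter for accuracy:

* **Watershed markers** come from h-maxima (depth 2 px) of the distance
  transform smoothed with σ = 3 px. Unsmoothed, the flat distance ridge of a
  capsule fragments into many regional maxima and the watershed saws tubules
  apart; smoothing merges the ridge into one marker while genuinely touching
  spheres keep separate maxima. Touching objects are split or, failing that,
  remain one region flagged by downstream shape filters — never silently
  merged into one metric row.
* **Half-maximum refinement**: the strong detection lowpass displaces a
  thresholded boundary outward. Each region's final contour is therefore
  re-extracted from a lightly smoothed image (σ = 1 px) at 50 % of the
  region's 99th-percentile feature amplitude. For a step edge (NS-TEM
  body) the half-maximum crossing sits at the true edge; for the cryo rim
  ridge the residual outward bias is ≈ 0.5 px. Benchmark mean absolute
  diameter error: 0.75 %.

A detection is `complete` only if its mask stays clear of a 2-px border
margin. Components with area-equivalent diameter below 20 nm are discarded
(below the smallest reported EV class and below reliable shape estimation).

## Morphometry

* **Diameter**: area-equivalent, `2·sqrt(A/π)`, from the exact shoelace
  polygon area — stable against boundary roughness; reported for *all*
  vesicles.
* **Ellipse axes**: from the second central moments of the filled polygon,
  computed exactly by Green's theorem (no rasterization); axes are those of
  the ellipse with the same normalized moments (`major = 4·sqrt(λ₁)`).
* **Feret diameters**: on the convex hull; the maximum is the largest
  vertex-pair distance, the minimum width is attained perpendicular to a
  hull edge (min over edges of the farthest vertex distance). Both are exact
  for polygons and verified against a 3600-angle projection sweep.
* **Roundness**: `4A/(π·major²)`, the classic particle-analysis
  "roundness"; equals minor/major for ellipses, 1 for circles, ≈ 0.51 for a
  capsule twice as long as wide. The alternative `4πA/P²` ("circularity") is
  selectable; the choice is recorded in run metadata. Roundness and the
  tubular flag (roundness strictly < 0.6 by default) are evaluated only for
  complete vesicles; condition summaries report both denominators (all, and
  complete-only).
* **Size modes**: Gaussian KDE with Silverman bandwidth; local maxima of the
  density on a 2048-point grid, ascending. Requires n ≥ 10; a constant
  sample degenerates to a single mode at that value.

## Membrane area

Background flattening and Gaussian smoothing (σ = 2 px) before Otsu keep the
threshold meaningful at coverages down to 1 % (raw-noise histograms defeat
Otsu when the foreground class is tiny); components under 20 px are
discarded. The fraction is an exact pixel count, invariant to intensity gain
and offset. The per-micrograph fraction is the sampling unit: condition
comparison uses the fold difference of group means — with an optional
mock-transfection background mean subtracted from both; the unsubtracted
fold is always reported alongside since either convention is defensible —
with uncertainty propagated to first order from the standard errors of the
means (validated against a Monte-Carlo ratio oracle), and an unpaired
two-sided Mann–Whitney test for significance.

## Bead assay

Beads are segmented on the reference (bead-marker) channel: Otsu threshold,
hole filling, distance-transform watershed, then diameter-range and
circularity (≥ 0.7) filters. Background is the per-channel median over
non-bead pixels — robust to sparse bright artifacts. The per-bead ratio is
(mean target − bg) / (mean ref − bg); per-bead ratios are averaged per
condition (mean-of-ratios, insensitive to bead size) and reported relative
to a control condition; the ratio-of-means variant is emitted alongside.

Rule-based exclusion replaces manual review, with a reason recorded for
every exclusion: out-of-range diameter, low circularity, reference signal
below a noise floor, saturated target pixels, reference underflow after
background subtraction, ids from an optional reviewer exclusion file, and
target-channel-only objects. The last category is found by segmenting the
target channel (connected components, no watershed — splitting would
fragment elongated blobs) and appending any blob without reference signal as
an excluded region; a blob whose appendage touches a bead also excludes that
bead as contaminated.

## Statistics

Student's t is the classic pooled-variance form (Welch by flag), two-tailed,
unpaired; zero-variance degenerate inputs are handled explicitly (p = 1 for
equal means, p = 0 flagged otherwise). Mann–Whitney uses the exact null for
min(n) ≤ 8 without ties and the tie-corrected normal approximation
otherwise. Bonferroni thresholds are α/m at full precision with m always
supplied by the caller; the display convention rounds to one significant
figure when that neither overstates the threshold nor tightens it by more
than 5 %, else truncates at two significant figures — reproducing the
conventional printed thresholds 0.0045 (0.05/11), 0.0009 (0.01/11), 0.00009
(0.001/11), and 0.007 (0.05/7) while never displaying a looser bound than
the exact value. `ratio_with_sd` implements first-order (delta-method)
propagation for a ratio of means, accurate when relative uncertainties are
small (checked against Monte-Carlo at 5 %).

## Topology filter

Loop compartments are derived from the N-terminus side by alternation;
termini are not counted as loops. With an extracellular N-terminus the four
inter-TM loops run IC/EC/IC/EC, which together with the size rules (both EC
loops > 300 aa, both IC loops < 25 aa, exactly five TM spans) realizes the
2+2+1 helix grouping. Inequalities are strict, exactly as printed; an
unknown N-terminus side is evaluated under the extracellular assumption
(the prominin convention) with a warning. Whether the > 300 aa rule applies
per loop or to the combined EC length is ambiguous in prose; per-loop is the
default and a combined mode is available.

## Known limitations

* Detection parameters were chosen on synthetic contrast; real micrographs
  (CTF ringing, stain artifacts, carbon edges) will need per-dataset
  threshold and size-range configuration.
* 2-D projections only: no 3-D shape inference, no membrane thickness
  estimation, no vesicle-level accounting inside the area-fraction estimate.
* The exact roundness formula, diameter estimator, and tubularity rule used
  by any particular published dataset may differ; both descriptor variants
  and a configurable threshold are exposed, and the choice is stamped into
  run metadata.
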