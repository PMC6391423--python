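# Methods

## The statistic

For each movie frame, all segmented cells form one population with mean
background-corrected fluorescence `m` and sample standard deviation `s`
(n−1 denominator; single-cell frames report `s = 0`, are flagged, and are
excluded from heterogeneity summaries).  Raw `s` mixes biological
cell-to-cell variability with setup-inherent noise: detection noise and a
size-dependent measurement bias that both grow with mean intensity.  A
homogeneous control promoter measured at several induction levels on the
same setup gives (mean, SD) points that are well described by a line
`s = a·m + b`; that ordinary-least-squares trend is the calibration model
(slope, intercept, r², number of points, residual SD).  The corrected
heterogeneity is

    s_corr = max(0, s − (a·m + b)),        CV = s_corr / m   (m > 0),

with negative pre-clamp values flagged.  Corrected SD is the reported
heterogeneity measure; variance is available as a derived column but is not
the primary statistic.  The correction is linear, so the CV is invariant
under a global rescaling of intensities applied to samples and controls
together (tested).

A population is called **homogeneous** when `s_corr` falls below 2
calibration-residual SDs at all four growth-phase marks — the corrected SD
is then indistinguishable from the scatter of the control around its own
trend line.

## Growth-phase marks

The growth curve is the cumulative Feret diameter (sum of per-cell maximum
pixel-center calipers × pixel size) over time.  Marks are located on the
log-curve's specific growth rate: mid-exponential is the median time of the
near-maximal-rate plateau (≥95% of max), transition the first later time
the rate drops below 50% of max, and the early/late stationary marks sit
25% and 90% of the way through the post-transition interval.  Leading
frames with no detected colony are trimmed first.  All four marks can be
overridden by explicit user times (validated, returned verbatim), because
sample-point choice by eye is common practice and must remain reproducible.
The stationary "grey zone" for maximum promoter activity defaults to
[early-stationary mark, end of recording].

## Synthetic microcolonies

Cells are 2D spherocylinders (default width 1 µm, birth length 2.5 µm,
division at 5 µm) elongating exponentially at ln 2 / doubling-time
(default 30 min) on a plane.  Division splits a cell along its axis with a
±5% uniform length asymmetry and small orientation jitter; daughters
inherit promoter state and concentration (concentration is intensive, so no
partition noise is applied).  Overlaps are resolved by fixed-point pairwise
repulsion along the line of closest approach between centerline segments
(0.55× over-relaxation, capped sweeps per substep); residual pairwise area
overlap stays below 10% of the smaller cell (tested).  Growth stops
globally at a stationary onset given as a time or a nutrient-capacity cell
count.

Expression follows d(conc)/dt = synthesis − λ·conc, where λ is the
elongation rate during growth and 0 in stationary phase, integrated
analytically over constant-state segments.  The telegraph promoter switches
OFF→ON at `k_on` and ON→OFF at `k_off` with exact exponential waiting
times inside every substep (not per-frame Bernoulli, so coarse frame
intervals stay correct).  Synthesis is `basal + state · rate · m · phase`,
with `phase` an exponential-phase multiplier that switches to 1 at
stationary onset, and `m` a per-cell lognormal extrinsic factor (unit mean,
configurable CV) drawn at birth.

### Presets (study conditions)

* **sunA-like heterogeneous**: telegraph with `k_on = 0.08`, `k_off = 0.02`
  per minute (stationary ON fraction 0.8, relaxation time 10 min),
  synthesis 2.7 AU/fl/min with exponential-phase multiplier 0.1, basal
  0.05, extrinsic CV 0.45.  Design: a frozen ON/OFF mixture at ON fraction
  f has concentration CV √((1−f)/f) = 0.5 at f = 0.8; switching during the
  ~150 min stationary window time-averages that to ≈ 0.19, and the
  extrinsic factor (0.45) tops the total back up to ≈ 0.5 at the stationary
  marks.  Realized ground-truth CVs across seeds fall in ≈ 0.41–0.52.
* **sunI-like homogeneous**: constitutive, synthesis 2.16 AU/fl/min
  (= 0.8 × 2.7, matching the heterogeneous preset's mean stationary
  synthesis), exponential-phase multiplier 0.35 so stationary means match
  within a few percent, no extrinsic noise.  Ground-truth CV ≤ 0.05.
* **calibration**: four constitutive colonies at synthesis 0.6 / 1.2 / 2.4
  / 4.8 AU/fl/min, spanning the samples' mean range from exponential to
  late stationary.

Movies default to 420 min at 6-min cadence (within the 5–7 min cadence of
the emulated experiments) with a 220-cell nutrient cap on a 512×512 px
canvas at 0.1 µm/px; calibration colonies use 360 min, 60 cells, 320×320 px.
These problem sizes keep a full multi-seed study to ~1 minute per seed
while leaving >200 cells at the stationary marks; the base configuration
object defaults to a 17-hour duration for users who want full-length
movies.

### Virtual microscope

Fluorescence = per-cell concentration painted on the true footprint,
Gaussian PSF (σ = 1 px), constant background (200 AU), Gaussian read noise
(SD 5 AU), quantized to 16 bits.  Phase contrast = background with dark
footprints (120 AU) rendered at 0.75× the true cell width, emulating the
bright cell-wall halo that phase optics produce between touching cells —
without it, a confluent colony rasterizes into one unresolvable blob,
which real phase images do not.  Saturation of >1% of cell pixels raises a
warning flag.

## Segmentation and measurement choices

* Threshold: Otsu on the phase image, floored at median − 6 robust noise
  SDs so frames whose foreground is too small for Otsu (or blank frames)
  do not threshold pure noise.
* Splitting: watershed on the Gaussian-smoothed (σ = 1 px) distance
  transform, seeded from 8-connected h-maxima with h = 0.15 × cell width
  in px.  The smoothing merges the EDT's diagonal-lattice ridge maxima
  inside a rod; h = 0.3 × width on the smoothed EDT suppresses true
  per-cell maxima (merging neighbours), hence the smaller default.
* Labels are then expanded 1 px into the background (never into each
  other): thresholded phase outlines sit inside the true boundary — halo
  rendering and the threshold both erode the apparent footprint — and the
  expansion brings per-cell Feret (hence the growth curve) within ~5% of
  true cell length.  Minimum region area defaults to 25% of a birth-cell
  footprint.
* Feret diameter uses pixel centers (single pixel → 0); the convex hull
  accelerates the max-distance search, with a brute-force fallback for
  degenerate (collinear) regions.
* Background: per-frame median outside labels dilated by 2 px; a fully
  confluent frame falls back, flagged, to the 1st percentile.
* Per-cell fluorescence is the mean (not integrated) intensity — a
  concentration proxy insensitive to cell size.  Corrected values may be
  negative and are not clamped.
* The pipeline's default calibration is *imaged*: the four control colonies
  are rendered and measured by the same segment→quantify path as the
  samples, every frame with ≥10 cells contributing one (mean, SD) point
  (~200 points).  This makes the trend subtraction capture exactly the
  setup noise the samples experience.  A direct table of per-cell draws
  with SD = slope·mean + intercept is also provided for controlled tests.

## Halo and microtiter conventions

Halo activity is the annulus area (halo minus colony disk), not the full
disk: the bacteriocin acts over the lawn surface and the producer colony
itself is not inhibited lawn.  Image measurement classifies each radius of
the median radial profile to the nearest of three intensity classes
(colony, clearing, lawn — boundaries at class midpoints); ring k spans
radii [k, k+1), so the leading-run length is the least-biased colony radius
and (last clearing ring + 1) the halo radius; accuracy is limited by the
±1 px rasterization quantum.  No clearing distinct from the lawn ⇒ halo
diameter set to colony diameter with a no-halo flag.  The path-length
reference (OD977 − OD900 of a 1 cm cuvette) is always caller-supplied.

## What the synthetic data does and does not show

The generator reproduces the features the statistic depends on: confluent
rod packing, growth-phase-dependent stochastic expression, dilution by
growth, linear setup noise, PSF/noise/quantization.  It does not model
uneven illumination, focus drift, photobleaching, phototoxicity, lysis,
motility, 3D colony growth, or segmentation-confounding debris.  Passing
tests therefore demonstrate the correctness of the measurement chain and
the correction algebra under a faithful but idealized imaging model — not
robustness to every real-microscope artifact.  Real mutant-strain effect
sizes are measurements of real biology and are outside what synthetic data
can reproduce; mutants enter only as user-chosen simulation presets.

## Numerical and reproducibility notes

All randomness flows from explicit integer seeds through numpy Generators;
the same seed and configuration give bit-identical ground truth, rendered
stacks and output files (the timestamped run.log is excluded from manifest
checksums).  Telegraph switching uses exact waiting times; concentration
updates use the closed-form linear-ODE solution, so no step-size error
accumulates.  Division triggers at length ≥ division length × (1 − 1e−9)
to absorb floating-point drift.  Degenerate inputs (blank frames, empty
masks, single-cell frames, zero-growth curves, confluent backgrounds) are
handled explicitly as flagged results or typed errors rather than NaNs.
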